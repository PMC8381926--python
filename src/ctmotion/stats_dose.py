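"""Double-examination precision statistics and DLP-based effective dose.

Precision follows the double-examination convention: repeat examinations
with patient repositioning have zero true migration, so the per-DOF spread
of the measured migrations estimates repeatability. The 95% bound uses a
two-sided Student-t coverage factor instead of 1.96 to avoid
underestimating the margin of error at small n (the t factor converges to
1.96 as n grows).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PrecisionReport",
    "DoseRecord",
    "DOF_LABELS",
    "t_factor",
    "precision_from_doubles",
    "effective_dose_from_dlp",
]

DOF_LABELS = ("tx_mm", "ty_mm", "tz_mm", "rx_deg", "ry_deg", "rz_deg")

#: pelvic DLP-to-effective-dose conversion factor, mSv per mGy·cm
PELVIS_CONVERSION_FACTOR = 0.0129


def t_factor(n: int, level: float = 0.95) -> float:
    """Two-sided Student-t coverage factor for ``n`` double examinations.

    Quantile of the t distribution with ``n - 1`` degrees of freedom at
    ``(1 + level) / 2``; tends to the normal factor (1.96 at 95%) for
    large n.
    """
    n = int(n)
    if n < 2:
        raise ValueError(f"need at least 2 examinations, got n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    return float(sps.t.ppf((1.0 + level) / 2.0, df=n - 1))


@dataclass(frozen=True)
class PrecisionReport:
    """Per-DOF double-examination precision.

    ``precision_bound = t_factor(n, level) * SD`` per degree of freedom;
    ``mean`` is reported as a bias check (it should be ~0 for true double
    examinations). SD uses the n-1 denominator.
    """

    n: int
    mean: np.ndarray
    sd: np.ndarray
    precision_bound: np.ndarray
    dof_labels: tuple = DOF_LABELS
    confidence_level: float = 0.95
    method_label: str = "ctma_beads"

    def __post_init__(self) -> None:
        for name in ("mean", "sd", "precision_bound"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(len(self.dof_labels))
            v.setflags(write=False)
            object.__setattr__(self, name, v)
        if np.any(self.sd < 0) or np.any(self.precision_bound < 0):
            raise ValueError("SD and precision bounds must be >= 0")
        if self.n < 2:
            raise ValueError("precision requires n >= 2")

    @property
    def coverage_factor(self) -> float:
        return t_factor(self.n, self.confidence_level)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dof": list(self.dof_labels),
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "precision_bound": self.precision_bound,
            "confidence_level": self.confidence_level,
            "method": self.method_label,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def __str__(self) -> str:
        lines = [
            f"Precision ({self.method_label}, n={self.n}, "
            f"{self.confidence_level:.0%} bound = t({self.n - 1}) x SD "
            f"= {self.coverage_factor:.3f} x SD):"
        ]
        for i, lab in enumerate(self.dof_labels):
            lines.append(
                f"  {lab:>6}: mean {self.mean[i]:+8.4f}  SD {self.sd[i]:7.4f}  "
                f"bound {self.precision_bound[i]:7.4f}"
            )
        return "\n".join(lines)


def precision_from_doubles(migrations, level: float = 0.95) -> PrecisionReport:
    """Precision report from a list of double-examination migration results.

    All results must share one coordinate frame and registration mode. The
    signed per-DOF values enter the SD directly, so any systematic bias
    shows up in the mean, not the spread. Permutation-invariant in the
    input order.
    """
    migrations = list(migrations)
    if len(migrations) < 2:
        raise ValueError(f"need >= 2 double examinations, got {len(migrations)}")
    frames = {m.frame for m in migrations}
    modes = {m.mode for m in migrations}
    if len(frames) > 1 or len(modes) > 1:
        raise ValueError(
            f"cannot pool mixed frames/modes: frames={sorted(frames)}, "
            f"modes={sorted(modes)}"
        )
    values = np.stack([m.dof for m in migrations])  # (n, 6)
    values = np.sort(values, axis=0)  # bit-exact permutation invariance
    n = values.shape[0]
    sd = values.std(axis=0, ddof=1)
    factor = t_factor(n, level)
    return PrecisionReport(
        n=n,
        mean=values.mean(axis=0),
        sd=sd,
        precision_bound=factor * sd,
        confidence_level=level,
        method_label=f"ctma_{modes.pop()}",
    )


@dataclass(frozen=True)
class DoseRecord:
    """Effective dose estimated from the dose-length product."""

    dlp_mgy_cm: float
    conversion_factor_msv_per_mgy_cm: float
    effective_dose_msv: float

    def to_dict(self) -> dict:
        return {
            "dlp_mgy_cm": float(self.dlp_mgy_cm),
            "conversion_factor_msv_per_mgy_cm": float(self.conversion_factor_msv_per_mgy_cm),
            "effective_dose_msv": float(self.effective_dose_msv),
        }


def effective_dose_from_dlp(
    dlp_mgy_cm: float, factor: float = PELVIS_CONVERSION_FACTOR
) -> DoseRecord:
    """Effective dose (mSv) = DLP (mGy·cm) x body-region conversion factor.

    The default factor is the pelvic value 0.0129 mSv per mGy·cm; pass a
    different factor for other body regions.
    """
    dlp = float(dlp_mgy_cm)
    if dlp < 0:
        raise ValueError(f"DLP must be >= 0, got {dlp}")
    if factor <= 0:
        raise ValueError(f"conversion factor must be > 0, got {factor}")
    return DoseRecord(
        dlp_mgy_cm=dlp,
        conversion_factor_msv_per_mgy_cm=float(factor),
        effective_dose_msv=dlp * float(factor),
    )
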