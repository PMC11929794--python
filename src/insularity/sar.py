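"""Species–area relationship: the log–log power model.

S = c·A^z is fitted as an ordinary least-squares regression of log10(S)
on log10(A); the slope is the SAR exponent z.  Reported alongside are the
intercept (log10 c), R², the regression F statistic with (1, n−2) degrees
of freedom, its p-value, and a t-based 95% confidence interval on z.
Zero-richness islands are dropped with a warning (their log is undefined;
shifting them would bias z).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SARFit", "fit_power_sar"]


@dataclass(frozen=True)
class SARFit:
    z: float
    log_c: float
    r2: float
    f_stat: float
    p_value: float
    z_ci: tuple[float, float]
    n: int

    def to_frame(self, response: str = "richness") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "response": response,
                    "z": self.z,
                    "log10_c": self.log_c,
                    "r2": self.r2,
                    "f_stat": self.f_stat,
                    "p_value": self.p_value,
                    "z_ci_lo": self.z_ci[0],
                    "z_ci_hi": self.z_ci[1],
                    "n": self.n,
                }
            ]
        )


def fit_power_sar(areas, richness) -> SARFit:
    """OLS of log10(richness) on log10(area).

    Requires ≥ 3 islands with positive area and richness; islands with
    zero richness are excluded (warning).  Raises on constant areas (the
    design would be singular).
    """
    a = np.asarray(areas, dtype=float)
    s = np.asarray(richness, dtype=float)
    if a.shape != s.shape:
        raise ValueError("areas and richness must have equal length")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    keep = s > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-richness islands from the SAR fit")
    a, s = a[keep], s[keep]
    if a.size < 3:
        raise ValueError("need at least 3 islands with positive richness")
    x = np.log10(a)
    if np.ptp(x) == 0:
        raise ValueError("all areas equal; SAR slope is unidentifiable")
    y = np.log10(s)
    if np.ptp(y) == 0:
        # constant richness: flat SAR, nothing explained
        return SARFit(z=0.0, log_c=float(y[0]), r2=0.0, f_stat=0.0,
                      p_value=1.0, z_ci=(0.0, 0.0), n=int(a.size))
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    return SARFit(
        z=float(res.params[1]),
        log_c=float(res.params[0]),
        r2=float(res.rsquared),
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        z_ci=(float(ci[1, 0]), float(ci[1, 1])),
        n=int(a.size),
    )
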