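"""Evaluation statistics: silique-count recalls and trait agreement."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = ["RecallReport", "recalls", "agreement"]


@dataclass
class RecallReport:
    """Silique-count recalls (%) between estimated, scanned and manual counts.

    ``re_el`` = estimated/scanned, ``re_lm`` = scanned/manual,
    ``re_em`` = estimated/manual, each × 100.
    """

    sn_e: int
    sn_l: int
    sn_m: int
    re_el: float
    re_lm: float
    re_em: float


def recalls(sn_e: int, sn_l: int, sn_m: int) -> RecallReport:
    """Compute the three recall ratios from the three silique counts."""
    if sn_l <= 0 or sn_m <= 0:
        raise ValueError("SN_L and SN_M must be positive")
    return RecallReport(
        sn_e=sn_e, sn_l=sn_l, sn_m=sn_m,
        re_el=100.0 * sn_e / sn_l,
        re_lm=100.0 * sn_l / sn_m,
        re_em=100.0 * sn_e / sn_m,
    )


def agreement(estimates, truths, r2_mode: str = "pearson") -> Tuple[float, float, float]:
    """Agreement between estimated and true values: (R², RMSE, R).

    ``r2_mode="pearson"`` reports the R² of the least-squares linear fit
    (the squared Pearson correlation); ``"identity"`` reports
    1 − SSE/SST of the raw predictions against the truth.
    """
    e = np.asarray(estimates, dtype=np.float64)
    t = np.asarray(truths, dtype=np.float64)
    if e.shape != t.shape or e.ndim != 1:
        raise ValueError("estimates and truths must be equal-length 1D sequences")
    if len(e) < 2:
        raise ValueError("agreement needs at least 2 pairs")
    if np.allclose(t, t[0]):
        raise ValueError("truth values are constant; correlation undefined")
    rmse = float(np.sqrt(np.mean((e - t) ** 2)))
    if np.allclose(e, e[0]):
        r = 0.0
    else:
        r = float(stats.pearsonr(e, t)[0])
    if r2_mode == "pearson":
        r2 = r * r
    elif r2_mode == "identity":
        sse = float(((t - e) ** 2).sum())
        sst = float(((t - t.mean()) ** 2).sum())
        r2 = 1.0 - sse / sst
    else:
        raise ValueError(f"unknown r2_mode {r2_mode!r}")
    return r2, rmse, r
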