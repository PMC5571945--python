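"""Test-retest agreement: Bland-Altman limits and the intraclass correlation.

Reproducibility of the MPI biomarker is summarized as the mean absolute
inter-scan difference M with limits of agreement M +/- 1.96 SD (the
Bland-Altman construction applied, as in the source protocol, to unsigned
differences), a paired t test on the repeated measurements, and the
intraclass correlation coefficient.  The ICC form is pinned to ICC(A,1) —
two-way random effects, absolute agreement, single measurement — because
the same scanner and procedure are used in both sessions and agreement,
not mere consistency, is the question.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps


@dataclass
class AgreementResult:
    n_subjects: int
    mean_abs_diff: float
    sd_abs_diff: float
    loa_low: float
    loa_high: float
    paired_t_p: float
    icc: float | None = None

    def __post_init__(self) -> None:
        # the Bland-Altman identity is part of the contract
        assert self.loa_low == self.mean_abs_diff - 1.96 * self.sd_abs_diff
        assert self.loa_high == self.mean_abs_diff + 1.96 * self.sd_abs_diff
        if self.icc is not None and self.icc > 1.0:
            raise ValueError(f"ICC cannot exceed 1, got {self.icc}")


def limits_of_agreement(m: float, sd: float) -> tuple[float, float]:
    """M +/- 1.96 SD."""
    return m - 1.96 * sd, m + 1.96 * sd


def bland_altman(pairs, signed: bool = False) -> AgreementResult:
    """Agreement between paired measurements (m1, m2).

    With ``signed=False`` (default) M and SD summarize the absolute
    inter-scan differences |m1 - m2|; ``signed=True`` gives the classical
    signed-difference variant.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (m1, m2) pairs")
    d = arr[:, 0] - arr[:, 1]
    if not signed:
        d = np.abs(d)
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = limits_of_agreement(m, sd)
    if np.allclose(arr[:, 0], arr[:, 1]):
        p = 1.0
    else:
        p = float(sps.ttest_rel(arr[:, 0], arr[:, 1]).pvalue)
    return AgreementResult(
        n_subjects=arr.shape[0],
        mean_abs_diff=m,
        sd_abs_diff=sd,
        loa_low=lo,
        loa_high=hi,
        paired_t_p=p,
    )


def icc(matrix) -> float:
    """ICC(A,1): two-way random effects, absolute agreement, single measurement.

    ``matrix`` is subjects x repeated measurements with no missing cells.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects with >= 2 measurements each")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not allowed")
    n, k = m.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), k),
            "session": np.tile(np.arange(k), n),
            "value": m.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="session", ratings="value"
    )
    value = float(table.loc[table["Type"] == "ICC(A,1)", "ICC"].iloc[0])
    return min(value, 1.0)


def test_retest(pairs) -> AgreementResult:
    """Full agreement summary (Bland-Altman + ICC) for two-session data."""
    res = bland_altman(pairs)
    res.icc = icc(np.asarray(pairs, dtype=float))
    return res
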