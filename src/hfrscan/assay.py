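"""Enhancer-blocking colony-assay analysis.

In the assay, a candidate boundary element is cloned between an LCR
enhancer and a neomycin-resistance reporter; blocking the enhancer
reduces the number of G418-resistant colonies.  Counts are normalized
per biological batch to that batch's mean empty-vector count, averaged
into a percent survival with a standard error, tested against the vector
control with an unpaired (pooled-variance) Student's t test, and binned
into activity tiers anchored on the control boundaries.

The module follows the model/results idiom: build an
:class:`EnhancerBlockingAssay` from assay records, call :meth:`fit`, and
read estimates, tests and tiers off the returned
:class:`BlockingAssayResults` (``summary()`` prints the full table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import AssayRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TierParams",
    "SurvivalResult",
    "TTestResult",
    "survival_ratios",
    "t_test_vs_vector",
    "classify_tier",
    "EnhancerBlockingAssay",
    "BlockingAssayResults",
]

TIER_LABELS = ("strong", "control-level", "weak", "none")


@dataclass(frozen=True)
class TierParams:
    """Survival-percentage cut-offs between activity tiers.

    The defaults encode the control anchors: elements at or below
    ``strong_max`` (50%) block more efficiently than the control
    boundaries; ``control_max`` (65%) bounds activity comparable to the
    controls; ``weak_max`` (75%) bounds residual activity; anything above
    is indistinguishable from no blocking.
    """

    strong_max: float = 50.0
    control_max: float = 65.0
    weak_max: float = 75.0

    def __post_init__(self) -> None:
        if not (self.strong_max < self.control_max < self.weak_max):
            raise ValueError("tier bounds must satisfy strong < control < weak")


@dataclass(frozen=True)
class SurvivalResult:
    """Vector-normalized survival of one construct."""

    construct: str
    survival_pct: float
    se_pct: float
    n: int
    tier: str


@dataclass(frozen=True)
class TTestResult:
    """Unpaired two-sample pooled-variance t test."""

    t_stat: float
    df: int
    p_value: float


def _ratios_by_construct(
    records: Sequence[AssayRecord], vector_label: str
) -> dict[str, list[float]]:
    """Per-replicate counts divided by their batch's mean vector count."""
    by_batch: dict[str, list[AssayRecord]] = {}
    for r in records:
        by_batch.setdefault(r.batch, []).append(r)
    constructs = sorted({r.construct for r in records})
    ratios: dict[str, list[float]] = {c: [] for c in constructs}
    for batch in sorted(by_batch):
        recs = by_batch[batch]
        vec = [r.colonies for r in recs if r.construct == vector_label]
        if not vec:
            raise ValueError(f"batch {batch!r} lacks vector control {vector_label!r}")
        vec_mean = float(np.mean(vec))
        if vec_mean <= 0:
            raise ValueError(f"batch {batch!r}: vector mean count is zero")
        present = {r.construct for r in recs}
        for c in constructs:
            if c not in present:
                logger.warning("construct %r absent from batch %r; batch skipped", c, batch)
        for r in sorted(recs, key=lambda r: (r.construct, r.replicate)):
            ratios[r.construct].append(r.colonies / vec_mean)
    return ratios


def survival_ratios(
    records: Sequence[AssayRecord],
    vector_label: str = "vector",
    tier_params: TierParams | None = None,
) -> list[SurvivalResult]:
    """Percent survival (mean of batch-normalized ratios x 100) with SE.

    Normalization is per biological batch, so rescaling all counts in a
    batch leaves every survival unchanged.  The vector control's survival
    is 100 by construction (it is normalized against itself); its SE is
    still computed across its own replicate ratios.
    """
    tier_params = tier_params or TierParams()
    ratios = _ratios_by_construct(records, vector_label)
    out = []
    for construct in sorted(ratios):
        vals = np.asarray(ratios[construct])
        n = len(vals)
        if construct == vector_label:
            pct = 100.0
        else:
            pct = 100.0 * float(vals.mean())
        se = 100.0 * float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        out.append(
            SurvivalResult(construct, pct, se, n, classify_tier(pct, tier_params))
        )
    return out


def t_test_vs_vector(
    construct_values: Iterable[float], vector_values: Iterable[float]
) -> TTestResult:
    """Classic unpaired Student's t test (pooled variance).

    df = n1 + n2 - 2; the p value is two-sided.
    """
    from scipy import stats

    x = np.asarray(list(construct_values), dtype=float)
    y = np.asarray(list(vector_values), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need >= 2 values for a t test")
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(res.statistic), len(x) + len(y) - 2, float(res.pvalue))


def classify_tier(survival_pct: float, params: TierParams | None = None) -> str:
    """Bin a percent survival into an enhancer-blocking activity tier."""
    params = params or TierParams()
    if survival_pct < 0:
        raise ValueError("survival percentage must be >= 0")
    if survival_pct <= params.strong_max:
        return "strong"
    if survival_pct <= params.control_max:
        return "control-level"
    if survival_pct <= params.weak_max:
        return "weak"
    return "none"


class EnhancerBlockingAssay:
    """Model of one enhancer-blocking experiment (counts -> survival).

    Parameters
    ----------
    records
        Colony counts, one per (construct, batch, replicate).
    vector_label
        Name of the empty-vector negative control present in every batch.
    test_on
        What the t test compares: ``"ratios"`` (batch-normalized, the
        default) or ``"counts"`` (raw colony counts).
    """

    def __init__(
        self,
        records: Sequence[AssayRecord],
        vector_label: str = "vector",
        tier_params: TierParams | None = None,
        test_on: str = "ratios",
    ) -> None:
        if test_on not in ("ratios", "counts"):
            raise ValueError("test_on must be 'ratios' or 'counts'")
        self.records = tuple(records)
        self.vector_label = vector_label
        self.tier_params = tier_params or TierParams()
        self.test_on = test_on

    @classmethod
    def from_table(cls, path, vector_label: str = "vector", **kwargs) -> "EnhancerBlockingAssay":
        from .io import read_assay_table

        return cls(read_assay_table(path, vector_label), vector_label, **kwargs)

    @classmethod
    def from_dataframe(cls, df, vector_label: str = "vector", **kwargs) -> "EnhancerBlockingAssay":
        records = [
            AssayRecord(str(r.construct), str(r.batch), int(r.replicate), int(r.colonies))
            for r in df.itertuples(index=False)
        ]
        return cls(records, vector_label, **kwargs)

    def fit(self) -> "BlockingAssayResults":
        survivals = survival_ratios(self.records, self.vector_label, self.tier_params)
        ratios = _ratios_by_construct(self.records, self.vector_label)
        if self.test_on == "ratios":
            samples = ratios
        else:
            samples = {}
            for r in self.records:
                samples.setdefault(r.construct, []).append(float(r.colonies))
        tests = {}
        vec = samples[self.vector_label]
        for construct, vals in samples.items():
            if construct == self.vector_label:
                continue
            tests[construct] = t_test_vs_vector(vals, vec)
        return BlockingAssayResults(self, survivals, tests, ratios)


class BlockingAssayResults:
    """Fitted survival estimates, significance tests and tiers."""

    def __init__(
        self,
        model: EnhancerBlockingAssay,
        survivals: list[SurvivalResult],
        tests: dict[str, TTestResult],
        ratios: dict[str, list[float]],
    ) -> None:
        self.model = model
        self.survivals = {s.construct: s for s in survivals}
        self.tests = tests
        self.ratios = ratios

    def __getitem__(self, construct: str) -> SurvivalResult:
        return self.survivals[construct]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for c, s in sorted(self.survivals.items()):
            t = self.tests.get(c)
            rows.append(
                {
                    "construct": c,
                    "survival_pct": s.survival_pct,
                    "se_pct": s.se_pct,
                    "n": s.n,
                    "t_stat": t.t_stat if t else np.nan,
                    "df": t.df if t else np.nan,
                    "p_value": t.p_value if t else np.nan,
                    "tier": s.tier,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [
            "Enhancer-blocking assay: percent colony survival vs empty vector",
            f"  vector control: {self.model.vector_label!r}; "
            f"t test on {self.model.test_on}",
            "",
            df.to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of percent survival with SE bars and tier lines."""
        from .plotting import plot_survival

        return plot_survival(self, ax=ax)
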