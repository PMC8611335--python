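"""Mixing-effect fitness statistics, survival/extinction analysis and
group contrasts.

Mixing effects compare a strain's spore production in a 1:1 mix with its
monoculture production from the same standard cell input.  For focal
strain ``i`` mixed with partner ``j`` at initial frequency ``f_i``:

    C_i(j) = log10( (s_mix_i / f_i) / s_pure_i )

i.e. the frequency-adjusted per-input spore output of ``i`` in the mix
relative to its monoculture output; 0 means mixing had no effect.  The
total-group mixing effect compares the mix's total output to the
frequency-weighted monoculture expectation:

    B_ij = log10( (s_mix_i + s_mix_j) / (f_i s_pure_i + f_j s_pure_j) )

Both statistics are scale-invariant (rescaling all counts by a common
factor leaves them unchanged) and strictly increasing in the mix counts.
A mix plating that yields zero spores is below the detection limit; its
C value is -inf and is flagged/censored rather than averaged.

Survival analysis summarises a ledger of per-population extinction cycles
into per-treatment surviving-count series, and tests the association of
extinction with partner category via Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixAssay",
    "MixingEffectResult",
    "OneSampleTestResult",
    "SurvivalLedger",
    "assays_from_table",
    "mixing_effect_one_way",
    "mixing_effect_total",
    "one_sample_test",
    "extinction_table",
    "extinction_test",
    "survival_curves",
    "contrasts_evolved_vs_anc",
    "contrasts_among_categories",
]


@dataclass
class MixAssay:
    """Monoculture and 1:1-mix spore counts for one strain pairing.

    Counts are spores recovered per standard cell input (~2.5e8 cells per
    spot).  ``s_pure_*`` and ``s_mix_*`` are per-replicate sequences of
    equal length; initial frequencies default to the 1:1 design.
    """

    strain_i: str
    strain_j: str
    s_pure_i: np.ndarray
    s_pure_j: np.ndarray
    s_mix_i: np.ndarray
    s_mix_j: np.ndarray
    f_i: float = 0.5
    f_j: float = 0.5

    def __post_init__(self) -> None:
        for name in ("s_pure_i", "s_pure_j", "s_mix_i", "s_mix_j"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
            setattr(self, name, arr)
        if not math.isclose(self.f_i + self.f_j, 1.0):
            raise ValueError("initial frequencies must sum to 1")
        if not (0 < self.f_i < 1):
            raise ValueError("initial frequencies must lie in (0, 1)")


@dataclass
class MixingEffectResult:
    """Per-replicate log10 mixing effects plus a one-sample test vs 0."""

    statistic_name: str  # "C_i(j)", "C_j(i)" or "B_ij"
    values: np.ndarray  # per replicate; may contain -inf (below detection)
    n_below_detection: int
    mean: float
    sem: float
    t: float
    p: float
    n_used: int
    degenerate: bool = False


@dataclass
class OneSampleTestResult:
    t: float
    p: float
    n: int
    mean: float
    degenerate: bool = False
    n_excluded_nonfinite: int = 0


def assays_from_table(table: pd.DataFrame) -> list[MixAssay]:
    """Build :class:`MixAssay` objects from a long ``spores.csv`` table.

    Expected columns: assay_id, replicate, strain, partner_or_NA, culture
    ({pure, mix}), spore_count, initial_frequency.  Each assay_id must
    contain exactly two strains with pure and mix counts per replicate.
    """
    assays = []
    for assay_id, sub in table.groupby("assay_id", observed=True):
        strains = sorted(sub["strain"].unique())
        if len(strains) != 2:
            raise ValueError(f"assay {assay_id!r} must involve exactly two strains")
        si, sj = strains
        sub = sub.sort_values("replicate")

        def counts(strain: str, culture: str) -> np.ndarray:
            sel = sub[(sub["strain"] == strain) & (sub["culture"] == culture)]
            return sel["spore_count"].to_numpy(dtype=np.float64)

        f_i = float(
            sub.loc[(sub["strain"] == si) & (sub["culture"] == "mix"),
                    "initial_frequency"].iloc[0]
        )
        assays.append(
            MixAssay(
                strain_i=si,
                strain_j=sj,
                s_pure_i=counts(si, "pure"),
                s_pure_j=counts(sj, "pure"),
                s_mix_i=counts(si, "mix"),
                s_mix_j=counts(sj, "mix"),
                f_i=f_i,
                f_j=1.0 - f_i,
            )
        )
    return assays


def _log10_ratio(numer: np.ndarray, denom: float | np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log10(numer / denom)


def mixing_effect_one_way(assay: MixAssay, focal: str) -> MixingEffectResult:
    """One-way mixing effect C_focal(partner), per replicate, with summary.

    Raises if the focal monoculture produced no spores (the statistic is
    undefined relative to a defective monoculture).  Zero mix counts give
    -inf, flagged as below the detection limit and excluded from the test.
    """
    if focal == assay.strain_i:
        pure, mix, f = assay.s_pure_i, assay.s_mix_i, assay.f_i
        name = f"C_{assay.strain_i}({assay.strain_j})"
    elif focal == assay.strain_j:
        pure, mix, f = assay.s_pure_j, assay.s_mix_j, assay.f_j
        name = f"C_{assay.strain_j}({assay.strain_i})"
    else:
        raise ValueError(f"focal strain {focal!r} not in assay")
    if np.any(pure == 0):
        raise ValueError(
            f"monoculture spore count of {focal!r} is zero: mixing effect "
            "undefined relative to defective monoculture"
        )
    values = _log10_ratio(mix / f, pure)
    return _summarize(name, values)


def mixing_effect_total(assay: MixAssay) -> MixingEffectResult:
    """Total-group mixing effect B_ij, per replicate, with summary."""
    expectation = assay.f_i * assay.s_pure_i + assay.f_j * assay.s_pure_j
    if np.any(expectation == 0):
        raise ValueError("frequency-weighted monoculture expectation is zero")
    totals = assay.s_mix_i + assay.s_mix_j
    values = _log10_ratio(totals, expectation)
    return _summarize(f"B_{assay.strain_i},{assay.strain_j}", values)


def _summarize(name: str, values: np.ndarray) -> MixingEffectResult:
    below = int(np.sum(np.isneginf(values)))
    finite = values[np.isfinite(values)]
    sem = (
        float(finite.std(ddof=1) / math.sqrt(finite.size))
        if finite.size > 1
        else math.nan
    )
    if finite.size >= 2:
        test = one_sample_test(values)
        t, p, degenerate = test.t, test.p, test.degenerate
    else:  # a single replicate carries no test
        t = p = math.nan
        degenerate = False
    return MixingEffectResult(
        statistic_name=name,
        values=values,
        n_below_detection=below,
        mean=float(finite.mean()) if finite.size else math.nan,
        sem=sem,
        t=t,
        p=p,
        n_used=int(finite.size),
        degenerate=degenerate,
    )


def one_sample_test(values: Sequence[float] | np.ndarray, null: float = 0.0) -> OneSampleTestResult:
    """Classical two-sided one-sample t-test against ``null``.

    Non-finite values (below-detection -inf) are excluded, with the count
    recorded.  Zero sample variance is degenerate: p = 0 for a nonzero
    mean difference, p = 1 when every value equals the null.
    """
    arr = np.asarray(values, dtype=np.float64)
    finite = arr[np.isfinite(arr)]
    n_excl = arr.size - finite.size
    if finite.size < 2:
        raise ValueError("one-sample test needs at least two finite values")
    mean = float(finite.mean())
    if finite.std(ddof=1) == 0:
        p = 1.0 if math.isclose(mean, null) else 0.0
        t = 0.0 if p == 1.0 else math.copysign(math.inf, mean - null)
        return OneSampleTestResult(
            t=t, p=p, n=int(finite.size), mean=mean, degenerate=True,
            n_excluded_nonfinite=n_excl,
        )
    res = stats.ttest_1samp(finite, popmean=null)
    return OneSampleTestResult(
        t=float(res.statistic), p=float(res.pvalue), n=int(finite.size), mean=mean,
        n_excluded_nonfinite=n_excl,
    )


@dataclass
class SurvivalLedger:
    """Per-population extinction record for the evolution experiment.

    ``table`` has columns treatment, population_id, extinction_cycle
    (NaN/None = survived to the end, i.e. censored at ``n_cycles``).
    Extinction at cycle c means the population produced no record at c or
    later (it failed at the development step of cycle c).
    """

    table: pd.DataFrame
    n_cycles: int = 10
    populations_per_treatment: int = 8

    def __post_init__(self) -> None:
        required = {"treatment", "population_id", "extinction_cycle"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"survival ledger missing columns: {sorted(missing)}")
        cyc = self.table["extinction_cycle"].dropna()
        if ((cyc < 1) | (cyc > self.n_cycles)).any():
            raise ValueError(
                f"extinction cycles must lie in [1, {self.n_cycles}] or be censored"
            )

    @property
    def n_populations(self) -> int:
        return len(self.table)

    @property
    def n_extinct(self) -> int:
        return int(self.table["extinction_cycle"].notna().sum())


def survival_curves(ledger: SurvivalLedger) -> dict:
    """Per-treatment surviving-count series plus extinction totals.

    The series value at cycle c is the number of populations that produced
    a developmental record at cycle c (extinction_cycle > c or censored);
    cycle 0 is the founding state.  Series are non-increasing by
    construction and validated as such.
    """
    cycles = np.arange(0, ledger.n_cycles + 1)
    series: dict[str, np.ndarray] = {}
    for trt, sub in ledger.table.groupby("treatment", observed=True):
        ext = sub["extinction_cycle"].to_numpy(dtype=np.float64)
        counts = np.array(
            [int(np.sum(~(ext <= c))) for c in cycles]  # NaN-safe: NaN <= c is False
        )
        if np.any(np.diff(counts) > 0):
            raise ValueError(f"inconsistent ledger: surviving count increases for {trt}")
        series[str(trt)] = counts
    n_total = ledger.n_populations
    n_extinct = ledger.n_extinct
    return {
        "cycles": cycles,
        "series": series,
        "n_total": n_total,
        "n_extinct": n_extinct,
        "percent_extinct": int(round(100.0 * n_extinct / n_total)) if n_total else 0,
    }


def extinction_table(
    ledger: SurvivalLedger, category_map: Mapping[str, str]
) -> np.ndarray:
    """2x2 extinction-by-category table.

    Rows: antagonist-partnered vs other; columns: extinct vs survived,
    i.e. ``[[extinct_antagonist, survived_antagonist],
    [extinct_other, survived_other]]``.
    """
    df = ledger.table.copy()
    cats = df["treatment"].map(dict(category_map))
    if cats.isna().any():
        missing = sorted(df.loc[cats.isna(), "treatment"].unique())
        raise ValueError(f"treatments without a category assignment: {missing}")
    is_ant = cats == "antagonist"
    extinct = df["extinction_cycle"].notna()
    table = np.array(
        [
            [int((is_ant & extinct).sum()), int((is_ant & ~extinct).sum())],
            [int((~is_ant & extinct).sum()), int((~is_ant & ~extinct).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0:
        raise ValueError("a partner category contains no populations")
    return table


def extinction_test(
    ledger: SurvivalLedger, category_map: Mapping[str, str]
) -> dict:
    """Fisher's exact test of extinction vs partner category (two-sided).

    The two-sided p sums the probabilities of all tables with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table.
    """
    table = extinction_table(ledger, category_map)
    res = stats.fisher_exact(table, alternative="two-sided")
    return {
        "table": table,
        "odds_ratio": float(res.statistic),
        "p": float(res.pvalue),
    }


def contrasts_evolved_vs_anc(
    evolved_assay_means: Sequence[float], anc_assay_means: Sequence[float]
) -> dict:
    """Two-sample two-tailed t-test, evolved-vs-ancestor, one trait.

    Units are per-assay group means (n = 3 assays per group).
    """
    a = np.asarray(evolved_assay_means, dtype=np.float64)
    b = np.asarray(anc_assay_means, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two assay-level means")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "p": 1.0, "n": (int(a.size), int(b.size)), "degenerate": True}
    res = stats.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "n": (int(a.size), int(b.size)),
        "degenerate": False,
    }


def contrasts_among_categories(
    groups: Mapping[str, Sequence[float]], tukey: bool = True
) -> dict:
    """One-way ANOVA plus two-tailed Tukey HSD over ≥ 2 groups, one trait.

    ``groups`` maps group label -> per-assay group means.  Returns the F
    statistic, ANOVA p, and (with ``tukey=True``) Tukey-adjusted p per
    unordered group pair.
    """
    labels = list(groups)
    samples = [np.asarray(groups[g], dtype=np.float64) for g in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        small = [g for g, s in zip(labels, samples) if s.size < 2]
        raise ValueError(f"groups with n < 2: {small}")
    f_res = stats.f_oneway(*samples)
    pairwise = {}
    if tukey:
        hsd = stats.tukey_hsd(*samples)
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                pairwise[(labels[i], labels[j])] = float(hsd.pvalue[i, j])
    return {
        "F": float(f_res.statistic),
        "p": float(f_res.pvalue),
        "tukey_p": pairwise,
    }
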