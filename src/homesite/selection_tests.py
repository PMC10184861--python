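"""Statistical tests for home-site advantage and per-ASV selection.

Two levels of inference:

* **Group level** — one-sample Wilcoxon signed-rank tests that LAI (or its
  deviation from the neutral expectation, or a source log-ratio) is centred
  away from zero within a group of recipient mice, with Benjamini-Hochberg
  FDR correction across groups.

* **Per-ASV level** — for each ASV, count how many recipient mice show an
  observed relative abundance above (positive selection) or below (negative
  selection) the load-weighted neutral expectation, and test that count
  against a sign-test null (success probability p0 = 0.5) with a one-sided
  exact binomial test; BH-correct across ASVs. Genotype dependence then
  compares selection calls between host genotypes (e.g. WT vs Rag1 knockout)
  using per-cage mean deviations as the experimental unit (cage mates share
  environment and coprophagy, so mice are not independent), and taxon
  enrichment among selected ASVs uses a 2x2 chi-square (or Fisher) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from homesite.community_io import OriginMap

__all__ = [
    "GroupTestResult",
    "AsvSelectionRecord",
    "test_group_nonzero",
    "benjamini_hochberg",
    "asv_selection_binomial",
    "asv_selection_table",
    "genotype_dependence",
    "enrichment_chisq",
    "EnrichmentResult",
]

DIRECTIONS = ("positive", "negative")


@dataclass
class GroupTestResult:
    """One-sample Wilcoxon test of a statistic's centre within one group."""

    group: str
    statistic_name: str
    n: int
    median: float
    p_wilcoxon: float
    q_bh: float | None = None


def test_group_nonzero(
    values: Sequence[float],
    group: str = "",
    statistic_name: str = "lai",
) -> GroupTestResult:
    """Two-sided one-sample Wilcoxon signed-rank test of median zero.

    Zeros are dropped before ranking (the classical Wilcoxon procedure); the
    exact null distribution is used for n <= 25 when the absolute values are
    untied, otherwise the normal approximation with continuity correction.
    All-zero input is degenerate: p = 1 with a warning.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1 or not np.isfinite(arr).all():
        raise ValueError("need at least one finite value")
    median = float(np.median(arr))
    nonzero = arr[arr != 0]
    if nonzero.size == 0:
        warnings.warn("all values are zero; Wilcoxon test degenerate, p = 1", stacklevel=2)
        return GroupTestResult(group, statistic_name, int(arr.size), median, 1.0)
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", alternative="two-sided", correction=True, method=method
    )
    return GroupTestResult(group, statistic_name, int(arr.size), median, float(res.pvalue))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR-adjusted q-values.

    Standard step-up with monotonicity enforcement: q >= p elementwise and
    the adjustment is order-preserving. p-values must lie in (0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AsvSelectionRecord:
    """Per-ASV consistency-of-deviation test against the neutral expectation.

    ``n_successes`` counts evaluable mice whose observed relative abundance
    deviates from the expectation in the tested direction (above for
    ``positive``, below for ``negative``); ties count as failures.
    """

    asv_id: str
    origin: str | None
    inoculum_id: str | None
    genotype: str | None
    direction: str
    n_mice_evaluated: int
    n_successes: int
    expected_relabund: float
    p_binomial: float
    q_bh: float | None = None
    selected: bool | None = None
    genotype_dependent: bool | None = None

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if not (0 <= self.n_successes <= self.n_mice_evaluated):
            raise ValueError("n_successes must lie in [0, n_mice_evaluated]")


def asv_selection_binomial(
    per_mouse_observed_relabund: Sequence[float],
    expected_relabund: float,
    direction: str = "positive",
    p0: float = 0.5,
    min_mice: int = 3,
    asv_id: str = "",
    origin: str | None = None,
    inoculum_id: str | None = None,
    genotype: str | None = None,
) -> AsvSelectionRecord:
    """One-sided exact binomial test for consistent deviation of one ASV.

    Each evaluable mouse is a Bernoulli trial: success iff its observed
    relative abundance exceeds (``positive``) or falls below (``negative``)
    the neutral expectation; ties (including both exactly zero) are
    failures — conservative for selection calls. Tests success probability
    > ``p0`` (default 0.5, the sign-test null: under neutrality a mouse is
    equally likely to land above or below its expectation).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie in (0, 1)")
    obs = np.asarray(per_mouse_observed_relabund, dtype=float)
    obs = obs[np.isfinite(obs)]
    n = obs.size
    if n < max(min_mice, 1):
        raise ValueError(f"only {n} evaluable mice; minimum is {max(min_mice, 1)}")
    if direction == "positive":
        k = int(np.sum(obs > expected_relabund))
    else:
        k = int(np.sum(obs < expected_relabund))
    p = stats.binomtest(k, n, p=p0, alternative="greater").pvalue
    return AsvSelectionRecord(
        asv_id=asv_id,
        origin=origin,
        inoculum_id=inoculum_id,
        genotype=genotype,
        direction=direction,
        n_mice_evaluated=n,
        n_successes=k,
        expected_relabund=float(expected_relabund),
        p_binomial=float(p),
    )


def asv_selection_table(
    observed_relabund: pd.DataFrame,
    expected_relabund: pd.Series,
    directions: Sequence[str] = DIRECTIONS,
    p0: float = 0.5,
    min_mice: int = 3,
    q_threshold: float = 0.05,
    origin_map: OriginMap | None = None,
    inoculum_id: str | None = None,
    genotype: str | None = None,
) -> pd.DataFrame:
    """Run the per-ASV binomial selection test over a whole cohort, vectorised.

    Parameters
    ----------
    observed_relabund : DataFrame
        ASVs x mice matrix of observed relative abundances (one column per
        evaluable mouse, one time point — never pool weeks within a mouse).
    expected_relabund : Series
        Per-ASV neutral expectation (mixture probabilities), indexed like
        the rows of ``observed_relabund``.
    directions : sequence of {"positive", "negative"}
        Each direction forms its own BH family.
    q_threshold : float
        BH q cut-off for the ``selected`` flag.

    Returns a tidy frame with one row per ASV x direction carrying the
    :class:`AsvSelectionRecord` fields.
    """
    expected = expected_relabund.reindex(observed_relabund.index)
    if expected.isna().any():
        missing = expected.index[expected.isna()].tolist()[:5]
        raise ValueError(f"expected relative abundance missing for ASVs such as {missing}")
    obs = observed_relabund.to_numpy(dtype=float)
    exp = expected.to_numpy(dtype=float)[:, None]
    n_mice = obs.shape[1]
    if n_mice < max(min_mice, 1):
        raise ValueError(f"cohort has {n_mice} mice; minimum is {max(min_mice, 1)}")
    frames = []
    for direction in directions:
        if direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        successes = (obs > exp) if direction == "positive" else (obs < exp)
        k = successes.sum(axis=1)
        # one-sided upper tail P[X >= k], X ~ Binomial(n, p0)
        p = stats.binom.sf(k - 1, n_mice, p0)
        q = benjamini_hochberg(p)
        frame = pd.DataFrame(
            {
                "asv_id": observed_relabund.index,
                "origin": (
                    origin_map.to_series().reindex(observed_relabund.index).to_numpy()
                    if origin_map is not None
                    else None
                ),
                "inoculum_id": inoculum_id,
                "genotype": genotype,
                "direction": direction,
                "n_mice_evaluated": n_mice,
                "n_successes": k,
                "expected_relabund": exp[:, 0],
                "p_binomial": p,
                "q_bh": q,
                "selected": q < q_threshold,
            }
        )
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def genotype_dependence(
    records_wt: pd.DataFrame,
    records_ko: pd.DataFrame,
    per_cage_deviations: pd.DataFrame,
    alpha_flag: float = 0.05,
    q_threshold: float = 0.05,
    min_cages: int = 2,
) -> pd.DataFrame:
    """Identify ASVs whose selection depends on host genotype.

    Two-stage screen mirroring the selection analysis: stage one flags ASVs
    whose binomial selection evidence is discordant between genotypes
    (unadjusted p < ``alpha_flag`` in one genotype, p >= ``alpha_flag`` in
    the other); stage two runs a two-sample Wilcoxon rank-sum test on
    per-cage mean deviations (observed - expected relative abundance,
    averaged within cage — the cage is the experimental unit) between
    genotypes for the flagged ASVs, BH-corrected across flagged ASVs.
    ``genotype_dependent`` requires both the flag and rank-sum q <
    ``q_threshold``.

    Parameters
    ----------
    records_wt, records_ko : DataFrame
        Outputs of :func:`asv_selection_table` for the two genotypes,
        restricted to a single direction.
    per_cage_deviations : DataFrame
        Long-form columns ``asv_id``, ``genotype``, ``cage_id``,
        ``deviation`` (per-cage mean observed - expected relative
        abundance). ASVs with fewer than ``min_cages`` cages in either
        genotype are skipped with a reason.
    """
    for name, rec in (("records_wt", records_wt), ("records_ko", records_ko)):
        if rec["direction"].nunique() > 1:
            raise ValueError(f"{name} mixes directions; restrict to one direction first")
    wt = records_wt.set_index("asv_id")
    ko = records_ko.set_index("asv_id")
    common = wt.index.intersection(ko.index)
    dev_groups = dict(tuple(per_cage_deviations.groupby(["asv_id", "genotype"], observed=True)))

    rows = []
    for asv in common:
        p_wt = wt.at[asv, "p_binomial"]
        p_ko = ko.at[asv, "p_binomial"]
        wt_sig, ko_sig = p_wt < alpha_flag, p_ko < alpha_flag
        flagged = wt_sig != ko_sig
        flag_class = ("WT_only" if wt_sig else "KO_only") if flagged else None
        row = {
            "asv_id": asv,
            "p_binomial_wt": p_wt,
            "p_binomial_ko": p_ko,
            "flagged": flagged,
            "flag_class": flag_class,
            "n_cages_wt": 0,
            "n_cages_ko": 0,
            "p_ranksum": np.nan,
            "q_ranksum": np.nan,
            "genotype_dependent": False,
            "skip_reason": None,
        }
        if flagged:
            dev_wt = dev_groups.get((asv, "WT"))
            dev_ko = dev_groups.get((asv, "Rag1KO"))
            n_wt = 0 if dev_wt is None else dev_wt["cage_id"].nunique()
            n_ko = 0 if dev_ko is None else dev_ko["cage_id"].nunique()
            row["n_cages_wt"], row["n_cages_ko"] = n_wt, n_ko
            if n_wt < min_cages or n_ko < min_cages:
                row["flagged"] = flagged
                row["skip_reason"] = f"fewer than {min_cages} cages in a genotype"
            else:
                x = dev_wt.groupby("cage_id", observed=True)["deviation"].mean().to_numpy()
                y = dev_ko.groupby("cage_id", observed=True)["deviation"].mean().to_numpy()
                res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
                row["p_ranksum"] = float(res.pvalue)
        rows.append(row)
    out = pd.DataFrame(rows)
    testable = out["p_ranksum"].notna()
    if testable.any():
        out.loc[testable, "q_ranksum"] = benjamini_hochberg(out.loc[testable, "p_ranksum"])
        out["genotype_dependent"] = out["flagged"] & (out["q_ranksum"] < q_threshold)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    statistic: float
    p_value: float
    method: str


def enrichment_chisq(
    selected_counts_by_class: Mapping[str, int] | Sequence[int],
    total_counts_by_class: Mapping[str, int] | Sequence[int],
    method: str = "chisq",
) -> EnrichmentResult:
    """Test whether selected ASVs are enriched in one class over another.

    Builds the 2x2 table (selected, not selected) x (class A, class B) —
    e.g. Bacteroidetes vs Firmicutes, or native vs non-native origin — and
    applies a Pearson chi-square test without Yates correction
    (``method="chisq"``), Fisher's exact test (``"fisher"``), or Fisher
    automatically whenever any expected cell count is below 5 (``"auto"``).
    """
    sel = np.asarray(
        list(selected_counts_by_class.values())
        if isinstance(selected_counts_by_class, Mapping)
        else selected_counts_by_class,
        dtype=np.int64,
    )
    tot = np.asarray(
        list(total_counts_by_class.values())
        if isinstance(total_counts_by_class, Mapping)
        else total_counts_by_class,
        dtype=np.int64,
    )
    if sel.shape != (2,) or tot.shape != (2,):
        raise ValueError("exactly two classes are required")
    if (sel < 0).any() or (sel > tot).any():
        raise ValueError("selected counts must lie in [0, total] per class")
    table = np.array([[sel[0], tot[0] - sel[0]], [sel[1], tot[1] - sel[1]]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin 2x2 table; enrichment test undefined")
    if method == "auto":
        expected = stats.contingency.expected_freq(table)
        method = "fisher" if (expected < 5).any() else "chisq"
    if method == "chisq":
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return EnrichmentResult(float(chi2), float(p), "chisq")
    if method == "fisher":
        odds, p = stats.fisher_exact(table)
        return EnrichmentResult(float(odds), float(p), "fisher")
    raise ValueError(f"method must be 'chisq', 'fisher' or 'auto', got {method!r}")
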