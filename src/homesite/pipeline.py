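"""Orchestration of the full analysis flow on real or synthetic inputs.

Stages mirror the analysis of a two-donor competition experiment:

1. **LAI stage** — per recipient sample, observed LAI against its inoculum's
   two donors; the load-weighted neutral expectation at the recipient's own
   read depth; the observed-minus-expected deviation; and per
   inoculum x genotype x week Wilcoxon group tests with BH correction
   across groups (one family per statistic).
2. **Selection stage** — per-ASV binomial tests of consistent deviation from
   the neutral expected relative abundance (both directions), genotype
   dependence on per-cage mean deviations when two genotypes are present,
   and origin-class enrichment among positively selected ASVs.
3. **Decay stage** — pairwise similarity vs host divergence time and the
   exponential decay fit.

All stages consume the file dialects of :mod:`homesite.community_io` or the
in-memory objects directly, and are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from homesite.community_io import DonorSample, FeatureTable, classify_asv_origin, rarefy
from homesite.neutral_model import (
    NeutralExpectation,
    donor_weight,
    expected_asv_abundance,
    expected_lai,
)
from homesite.selection_tests import (
    asv_selection_table,
    benjamini_hochberg,
    enrichment_chisq,
    genotype_dependence,
    test_group_nonzero,
)
from homesite.similarity import lai

logger = logging.getLogger("homesite")

__all__ = ["LaiStageResult", "SelectionStageResult", "run_lai_stage", "run_selection_stage"]


def _donor_ids(metadata: pd.DataFrame, inoculum_id: str) -> tuple[str, str]:
    rows = metadata[metadata["inoculum_id"] == inoculum_id]
    nat = rows.loc[rows["role"] == "donor_native", "sample_id"].tolist()
    non = rows.loc[rows["role"] == "donor_nonnative", "sample_id"].tolist()
    if len(nat) != 1 or len(non) != 1:
        raise ValueError(
            f"inoculum {inoculum_id!r} needs exactly one native and one non-native donor, "
            f"found {len(nat)} and {len(non)}"
        )
    return nat[0], non[0]


def _mixture_weight(loads: Mapping[str, DonorSample], nat_id: str, non_id: str) -> float:
    try:
        nat, non = loads[nat_id], loads[non_id]
    except KeyError as exc:
        raise KeyError(f"donor sample {exc.args[0]!r} missing from the load table") from None
    return donor_weight(nat.load, nat.mass, non.load, non.mass)


@dataclass
class LaiStageResult:
    """Per-sample LAI records and per-group Wilcoxon tests."""

    records: pd.DataFrame  # one row per recipient sample x metric
    group_tests: pd.DataFrame


def run_lai_stage(
    table: FeatureTable,
    metadata: pd.DataFrame,
    loads: Mapping[str, DonorSample],
    metrics: Sequence[str] = ("jaccard",),
    n_reps: int = 1000,
    seed: int | None = None,
    rarefy_depth: int | None = None,
    detection_min: int = 1,
) -> LaiStageResult:
    """Observed and expected LAI for every recipient sample, plus group tests.

    The neutral expectation is Monte-Carlo simulated at each recipient's own
    read depth (expectations are cached per inoculum x depth x metric, so
    recipients sequenced to the same depth share one simulation set). When
    ``rarefy_depth`` is given, the whole table is first rarefied to that
    common depth.
    """
    if rarefy_depth is not None:
        table = rarefy(table, rarefy_depth, seed=seed)
        metadata = metadata[metadata["sample_id"].isin(table.sample_ids)]
    recipients = metadata[metadata["role"] == "recipient"]
    if recipients.empty:
        raise ValueError("no recipient samples in metadata")

    rng = np.random.default_rng(seed)
    rows = []
    cache: dict[tuple, NeutralExpectation] = {}
    for inoculum_id, group in recipients.groupby("inoculum_id", observed=True):
        nat_id, non_id = _donor_ids(metadata, inoculum_id)
        w = _mixture_weight(loads, nat_id, non_id)
        nat_prof = table.column(nat_id)
        non_prof = table.column(non_id)
        logger.info(
            "LAI stage: inoculum %s, %d recipients, w_native=%.4f", inoculum_id, len(group), w
        )
        for row in group.itertuples():
            rec = table.column(row.sample_id)
            depth = int(rec.sum())
            for metric in metrics:
                observed = lai(
                    rec, nat_prof, non_prof, metric=metric, detection_min=detection_min,
                    recipient_sample_id=row.sample_id,
                )
                key = (inoculum_id, depth, metric)
                if key not in cache:
                    cache[key] = expected_lai(
                        depth, nat_prof, non_prof, w, n_reps=n_reps,
                        seed=np.random.default_rng(rng.integers(2**31)),
                        metric=metric, inoculum_id=inoculum_id,
                    )
                expectation = cache[key]
                rows.append(
                    {
                        "sample_id": row.sample_id,
                        "inoculum_id": inoculum_id,
                        "genotype": row.genotype,
                        "week": row.week,
                        "metric": metric,
                        "depth": depth,
                        "sim_native": observed.sim_native,
                        "sim_nonnative": observed.sim_nonnative,
                        "lai": observed.lai,
                        "expected_lai": expectation.expected_lai,
                        "sd_expected_lai": expectation.sd_lai,
                        "lai_deviation": observed.lai - expectation.expected_lai,
                    }
                )
    records = pd.DataFrame(rows)

    tests = []
    for (inoculum_id, genotype, week, metric), group in records.groupby(
        ["inoculum_id", "genotype", "week", "metric"], observed=True
    ):
        label = f"{inoculum_id}|{genotype}|week{week}|{metric}"
        for statistic in ("lai", "lai_deviation"):
            result = test_group_nonzero(group[statistic], group=label, statistic_name=statistic)
            tests.append(
                {
                    "group": label,
                    "inoculum_id": inoculum_id,
                    "genotype": genotype,
                    "week": week,
                    "metric": metric,
                    "statistic": statistic,
                    "n": result.n,
                    "median": result.median,
                    "p_wilcoxon": result.p_wilcoxon,
                }
            )
    group_tests = pd.DataFrame(tests)
    if not group_tests.empty:
        group_tests["q_bh"] = np.nan
        for statistic, idx in group_tests.groupby("statistic", observed=True).groups.items():
            group_tests.loc[idx, "q_bh"] = benjamini_hochberg(group_tests.loc[idx, "p_wilcoxon"])
    return LaiStageResult(records, group_tests)


@dataclass
class SelectionStageResult:
    """Per-ASV selection records and downstream genotype/enrichment tests."""

    records: pd.DataFrame
    genotype_tests: pd.DataFrame | None
    enrichment: pd.DataFrame
    week_used: int


def _final_week(metadata: pd.DataFrame) -> int:
    return int(metadata.loc[metadata["role"] == "recipient", "week"].max())


def run_selection_stage(
    table: FeatureTable,
    metadata: pd.DataFrame,
    loads: Mapping[str, DonorSample],
    week: int | None = None,
    p0: float = 0.5,
    min_mice: int = 3,
    q_threshold: float = 0.05,
    alpha_flag: float = 0.05,
    detection_min: int = 1,
) -> SelectionStageResult:
    """Per-ASV selection inference against the neutral expectation.

    Only ASVs present in the inoculum mixture (neutral expected relative
    abundance > 0) are testable. One time point per mouse enters the tests —
    by default the final collection week (weeks are never pooled within a
    mouse). Genotype dependence runs per direction whenever both genotypes
    have recipients; enrichment compares the proportion of positively
    selected ASVs between native-only and non-native-only origin classes.
    """
    recipients = metadata[metadata["role"] == "recipient"]
    if recipients.empty:
        raise ValueError("no recipient samples in metadata")
    week = _final_week(metadata) if week is None else int(week)
    at_week = recipients[recipients["week"] == week]
    if at_week.empty:
        raise ValueError(f"no recipient samples at week {week}")
    if at_week.duplicated("mouse_id").any():
        raise ValueError(f"multiple samples per mouse at week {week}; one per mouse required")

    all_records = []
    genotype_frames = []
    enrichment_rows = []
    for inoculum_id, group in at_week.groupby("inoculum_id", observed=True):
        nat_id, non_id = _donor_ids(metadata, inoculum_id)
        w = _mixture_weight(loads, nat_id, non_id)
        nat_prof, non_prof = table.column(nat_id), table.column(non_id)
        expected = expected_asv_abundance(nat_prof, non_prof, w)
        origin_map = classify_asv_origin(table, [nat_id], [non_id], detection_min=detection_min)
        testable = expected.index[expected > 0]
        logger.info(
            "selection stage: inoculum %s week %d, %d testable ASVs (of %d), %d mice",
            inoculum_id, week, len(testable), len(expected), len(group),
        )

        per_geno: dict[str, pd.DataFrame] = {}
        deviations_long = []
        for genotype, mice in group.groupby("genotype", observed=True):
            obs = table.select_samples(mice["sample_id"].tolist()).relative_abundance()
            obs = obs.loc[testable]
            records = asv_selection_table(
                obs,
                expected.loc[testable],
                p0=p0,
                min_mice=min_mice,
                q_threshold=q_threshold,
                origin_map=origin_map,
                inoculum_id=inoculum_id,
                genotype=genotype,
            )
            per_geno[genotype] = records
            all_records.append(records)
            dev = obs.sub(expected.loc[testable], axis=0)  # ASV x mouse deviations
            cage_of = mice.set_index("sample_id")["cage_id"]
            long = dev.T.assign(cage_id=cage_of.reindex(dev.columns).to_numpy()).melt(
                id_vars="cage_id", var_name="asv_id", value_name="deviation", ignore_index=False
            )
            long["genotype"] = genotype
            deviations_long.append(long.reset_index(drop=True))

        if len(per_geno) == 2 and {"WT", "Rag1KO"} == set(per_geno):
            per_cage = (
                pd.concat(deviations_long, ignore_index=True)
                .groupby(["asv_id", "genotype", "cage_id"], observed=True)["deviation"]
                .mean()
                .reset_index()
            )
            for direction in ("positive", "negative"):
                wt = per_geno["WT"].query("direction == @direction")
                ko = per_geno["Rag1KO"].query("direction == @direction")
                gdep = genotype_dependence(
                    wt, ko, per_cage, alpha_flag=alpha_flag, q_threshold=q_threshold
                )
                gdep.insert(0, "inoculum_id", inoculum_id)
                gdep.insert(1, "direction", direction)
                genotype_frames.append(gdep)
        elif len(per_geno) == 1:
            logger.info("selection stage: single genotype in %s; genotype-dependence skipped", inoculum_id)

        for genotype, records in per_geno.items():
            pos = records.query("direction == 'positive'").set_index("asv_id")
            for_origin = pos["origin"]
            sel = pos["selected"]
            n_nat, n_non = int((for_origin == "native_only").sum()), int((for_origin == "nonnative_only").sum())
            if n_nat and n_non:
                sel_nat = int(sel[for_origin == "native_only"].sum())
                sel_non = int(sel[for_origin == "nonnative_only"].sum())
                row = {
                    "inoculum_id": inoculum_id,
                    "genotype": genotype,
                    "comparison": "native_only_vs_nonnative_only",
                    "selected_native": sel_nat,
                    "total_native": n_nat,
                    "selected_nonnative": sel_non,
                    "total_nonnative": n_non,
                }
                try:
                    result = enrichment_chisq([sel_nat, sel_non], [n_nat, n_non], method="auto")
                    row.update(
                        statistic=result.statistic, p_value=result.p_value, method=result.method
                    )
                except ValueError:  # e.g. nothing selected in either class
                    logger.info(
                        "enrichment undefined for %s/%s (zero margin)", inoculum_id, genotype
                    )
                    row.update(statistic=np.nan, p_value=np.nan, method="undefined")
                enrichment_rows.append(row)

    return SelectionStageResult(
        records=pd.concat(all_records, ignore_index=True),
        genotype_tests=pd.concat(genotype_frames, ignore_index=True) if genotype_frames else None,
        enrichment=pd.DataFrame(enrichment_rows),
        week_used=week,
    )
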