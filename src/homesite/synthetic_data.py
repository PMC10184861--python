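"""Synthetic microbiota-competition studies for end-to-end pipeline testing.

Emulates the design of a two-donor gnotobiotic competition experiment: two
donor fecal communities with partially overlapping ASV sets and log-normal
rank-abundance shapes, distinct absolute bacterial loads, mixed by weight
into one inoculum, and cohorts of ex-germ-free recipient mice (optionally of
two host genotypes, housed in cages) whose communities assemble either
neutrally or under per-ASV selection.

A recipient's assembly probabilities are

    q_i  proportional to  [w p_i^nat + (1-w) p_i^non] * s_i(genotype) * c_i(cage)

where w is the load-derived mixing weight, s_i a multiplicative per-ASV
selection factor for the recipient's genotype (s = 1 everywhere is exact
neutrality, matching the neutral model's multinomial distribution by
construction), and c_i a per-cage log-normal multiplicative effect shared by
cage mates (off by default). Reads are a multinomial draw at the configured
depth. ASV identifiers are deterministic ("nat_0000", "non_0000",
"sh_0000"), so selection maps can name individual ASVs or whole origin
classes. All randomness flows from one seed through spawned, never-reused
child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from homesite.community_io import (
    DonorSample,
    FeatureTable,
    write_feature_table,
)
from homesite.neutral_model import MixtureDesign

__all__ = [
    "SyntheticStudyConfig",
    "SyntheticDonor",
    "SyntheticStudy",
    "generate_donor",
    "generate_recipients",
    "generate_study",
]

_ORIGIN_CLASS_KEYS = {"native_only", "nonnative_only", "shared"}


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of one synthetic competition study.

    Defaults describe a neutral study at the scale of the emulated
    experiments: two donors of 150 ASVs each sharing 10% of them, log-normal
    abundances (sigma = 2), loads log-uniform over 1e8-1e10 copies/g, 25 mg
    of feces per donor, and 20 recipient mice per genotype in 5 cages
    sequenced at 5,000 reads.

    ``selection`` maps genotype -> {key -> s} where a key is either an ASV
    id or an origin class name ("native_only", "nonnative_only", "shared")
    applying s to the whole class; s > 0, s = 1 neutral.
    """

    n_asvs_per_donor: int = 150
    overlap_fraction: float = 0.10
    abundance_lognormal_sigma: float = 2.0
    load_range: tuple[float, float] = (1e8, 1e10)
    fecal_mass_grams: float = 0.025
    n_recipients: int = 20  # mice per genotype
    n_cages: int = 5  # cages per genotype
    genotypes: tuple[str, ...] = ("WT",)
    selection: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    cage_effect_sigma: float = 0.0
    read_depth: int = 5000
    weeks: tuple[int, ...] = (4,)
    inoculum_id: str = "mix1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_asvs_per_donor < 1:
            raise ValueError("n_asvs_per_donor must be >= 1")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.abundance_lognormal_sigma < 0:
            raise ValueError("abundance_lognormal_sigma must be >= 0")
        lo, hi = self.load_range
        if not (0 < lo <= hi):
            raise ValueError("load_range must satisfy 0 < min <= max")
        if self.fecal_mass_grams <= 0:
            raise ValueError("fecal_mass_grams must be > 0")
        if self.n_recipients < 1 or self.n_cages < 1 or self.read_depth < 1:
            raise ValueError("n_recipients, n_cages and read_depth must be >= 1")
        if self.n_cages > self.n_recipients:
            raise ValueError("cannot have more cages than recipients")
        if not self.genotypes:
            raise ValueError("at least one genotype is required")
        if self.cage_effect_sigma < 0:
            raise ValueError("cage_effect_sigma must be >= 0")
        if not self.weeks:
            raise ValueError("at least one collection week is required")
        for genotype, smap in self.selection.items():
            if genotype not in self.genotypes:
                raise ValueError(f"selection map for unknown genotype {genotype!r}")
            for key, s in smap.items():
                if not (s > 0 and np.isfinite(s)):
                    raise ValueError(f"selection factor for {key!r} must be positive, got {s!r}")

    # -- ASV universe ------------------------------------------------------

    @property
    def n_shared(self) -> int:
        return round(self.overlap_fraction * self.n_asvs_per_donor)

    def asv_universe(self) -> tuple[list[str], pd.Series]:
        """Deterministic ASV ids and their true origin classes."""
        n_excl = self.n_asvs_per_donor - self.n_shared
        nat = [f"nat_{i:04d}" for i in range(n_excl)]
        non = [f"non_{i:04d}" for i in range(n_excl)]
        shared = [f"sh_{i:04d}" for i in range(self.n_shared)]
        ids = nat + non + shared
        origin = pd.Series(
            ["native_only"] * len(nat) + ["nonnative_only"] * len(non) + ["shared"] * len(shared),
            index=ids,
        )
        return ids, origin

    def selection_factors(self, genotype: str) -> pd.Series:
        """Per-ASV multiplicative selection factors s for one genotype."""
        ids, origin = self.asv_universe()
        s = pd.Series(1.0, index=ids)
        for key, value in self.selection.get(genotype, {}).items():
            if key in _ORIGIN_CLASS_KEYS:
                s[origin == key] = value
            elif key in s.index:
                s[key] = value
            else:
                raise KeyError(f"selection key {key!r} is neither an ASV id nor an origin class")
        return s


@dataclass(frozen=True)
class SyntheticDonor:
    """A generated donor: sequenced counts, load record, and ground truth."""

    counts: pd.Series  # on the full ASV universe (zeros outside own set)
    donor: DonorSample
    true_relabund: pd.Series  # true composition on the full universe


def generate_donor(
    config: SyntheticStudyConfig,
    role: str,
    seed: int | np.random.SeedSequence | None = None,
) -> SyntheticDonor:
    """Generate one donor community with its absolute load.

    The donor's ASV set is its exclusive block plus the shared block of the
    universe; true relative abundances are log-normal(0, sigma) normalised,
    sequenced counts a multinomial draw at the configured read depth, and
    the load log-uniform over ``load_range``.
    """
    if role not in ("donor_native", "donor_nonnative"):
        raise ValueError("role must be 'donor_native' or 'donor_nonnative'")
    rng = np.random.default_rng(seed)
    ids, origin = config.asv_universe()
    own_class = "native_only" if role == "donor_native" else "nonnative_only"
    own = origin.index[(origin == own_class) | (origin == "shared")]
    sigma = config.abundance_lognormal_sigma
    raw = np.exp(rng.normal(0.0, sigma, size=len(own))) if sigma > 0 else np.ones(len(own))
    rel = pd.Series(0.0, index=ids)
    rel[own] = raw / raw.sum()
    counts = pd.Series(
        rng.multinomial(config.read_depth, rel.to_numpy()), index=ids, dtype=np.int64
    )
    lo, hi = config.load_range
    load = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    sample_id = "donor_nat" if role == "donor_native" else "donor_non"
    return SyntheticDonor(
        counts=counts,
        donor=DonorSample(sample_id, load, config.fecal_mass_grams),
        true_relabund=rel,
    )


def generate_recipients(
    donor_pair: tuple[SyntheticDonor, SyntheticDonor],
    config: SyntheticStudyConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate recipient cohorts assembled from the donor mixture.

    One sample per mouse per collection week (independent draws across
    weeks). Mice are assigned round-robin to ``n_cages`` cages per genotype;
    cage effects (when ``cage_effect_sigma`` > 0) perturb each cage's
    assembly probabilities by an ASV-wise log-normal factor shared by cage
    mates. Returns the recipient feature table and a metadata frame.
    """
    native, nonnative = donor_pair
    w = MixtureDesign(config.inoculum_id, native.donor, nonnative.donor).weight_native
    # Assembly uses the donors' *sequenced* compositions: the generator defines
    # each donor community as its observed profile, so donor-profile measurement
    # error is deliberately not emulated and a neutral study is distributed
    # exactly as the neutral model reconstructed from the same table.
    base = w * (native.counts / native.counts.sum()) + (1.0 - w) * (
        nonnative.counts / nonnative.counts.sum()
    )
    base = base / base.sum()
    ids = base.index

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for genotype in config.genotypes:
        s = config.selection_factors(genotype).reindex(ids).to_numpy()
        geno_seq, cage_seq = root.spawn(2)
        cage_rng = np.random.default_rng(cage_seq)
        cage_factors = {}
        for c in range(config.n_cages):
            if config.cage_effect_sigma > 0:
                cage_factors[c] = np.exp(
                    cage_rng.normal(0.0, config.cage_effect_sigma, size=len(ids))
                )
            else:
                cage_factors[c] = np.ones(len(ids))
        mouse_seqs = geno_seq.spawn(config.n_recipients)
        for m in range(config.n_recipients):
            cage = m % config.n_cages
            q = base.to_numpy() * s * cage_factors[cage]
            q = q / q.sum()
            mouse_rng = np.random.default_rng(mouse_seqs[m])
            mouse_id = f"{genotype}_m{m:02d}"
            cage_id = f"{genotype}_c{cage}"
            for week in config.weeks:
                sample_id = f"{mouse_id}_w{week}"
                columns[sample_id] = mouse_rng.multinomial(config.read_depth, q)
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "mouse_id": mouse_id,
                        "cage_id": cage_id,
                        "genotype": genotype,
                        "role": "recipient",
                        "inoculum_id": config.inoculum_id,
                        "week": week,
                    }
                )
    table = FeatureTable(pd.DataFrame(columns, index=ids))
    return table, pd.DataFrame(meta_rows)


@dataclass(frozen=True)
class SyntheticStudy:
    """A full generated study: tables, metadata, loads, design and truth."""

    table: FeatureTable  # donors + recipients
    metadata: pd.DataFrame
    loads: dict[str, DonorSample]
    mixture: MixtureDesign
    truth: pd.DataFrame
    config: SyntheticStudyConfig

    @property
    def donor_native_id(self) -> str:
        return self.mixture.native.sample_id

    @property
    def donor_nonnative_id(self) -> str:
        return self.mixture.nonnative.sample_id


def generate_study(config: SyntheticStudyConfig, out_dir: str | Path | None = None) -> SyntheticStudy:
    """Generate a complete study bundle; optionally write it to ``out_dir``.

    Files written (TSV dialects consumed by :mod:`homesite.community_io`):
    ``feature_table.tsv`` (donor + recipient columns), ``metadata.tsv``,
    ``loads.tsv`` and ``truth.tsv`` (asv_id, origin, per-genotype s, and the
    expected selection call).
    """
    root = np.random.SeedSequence(config.seed)
    nat_seq, non_seq, rec_seq = root.spawn(3)
    native = generate_donor(config, "donor_native", nat_seq)
    nonnative = generate_donor(config, "donor_nonnative", non_seq)
    recipients, meta = generate_recipients((native, nonnative), config, rec_seq)

    frame = recipients.to_dataframe()
    frame.insert(0, native.donor.sample_id, native.counts)
    frame.insert(1, nonnative.donor.sample_id, nonnative.counts)
    table = FeatureTable(frame)

    donor_meta = pd.DataFrame(
        [
            {
                "sample_id": native.donor.sample_id,
                "mouse_id": "donor_nat_mouse",
                "cage_id": "donor_nat_cage",
                "genotype": "WT",
                "role": "donor_native",
                "inoculum_id": config.inoculum_id,
                "week": 0,
            },
            {
                "sample_id": nonnative.donor.sample_id,
                "mouse_id": "donor_non_mouse",
                "cage_id": "donor_non_cage",
                "genotype": "WT",
                "role": "donor_nonnative",
                "inoculum_id": config.inoculum_id,
                "week": 0,
            },
        ]
    )
    metadata = pd.concat([donor_meta, meta], ignore_index=True)

    _, origin = config.asv_universe()
    truth = pd.DataFrame({"asv_id": origin.index, "origin": origin.to_numpy()})
    calls = np.full(len(truth), "none", dtype=object)
    for genotype in config.genotypes:
        s = config.selection_factors(genotype).to_numpy()
        truth[f"s_{genotype}"] = s
        calls[s > 1] = "positive"
        calls[(s < 1) & (calls != "positive")] = "negative"
    truth["expected_call"] = calls

    mixture = MixtureDesign(config.inoculum_id, native.donor, nonnative.donor)
    study = SyntheticStudy(
        table=table,
        metadata=metadata,
        loads={d.sample_id: d for d in (native.donor, nonnative.donor)},
        mixture=mixture,
        truth=truth,
        config=config,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, out / "feature_table.tsv")
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "sample_id": d.sample_id,
                    "load_copies_per_gram": d.load,
                    "mass_grams": d.mass,
                }
                for d in study.loads.values()
            ]
        ).to_csv(out / "loads.tsv", sep="\t", index=False)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return study
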