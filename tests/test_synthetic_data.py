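"""Synthetic study generator: contracts, determinism, neutral equivalence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from homesite.community_io import classify_asv_origin, read_donor_loads, read_feature_table, read_sample_metadata
from homesite.synthetic_data import (
    SyntheticStudyConfig,
    generate_donor,
    generate_recipients,
    generate_study,
)


class TestConfig:
    def test_defaults_valid(self):
        config = SyntheticStudyConfig()
        assert config.n_shared == 15
        ids, origin = config.asv_universe()
        assert len(ids) == 2 * (150 - 15) + 15
        assert origin.value_counts()["shared"] == 15

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            SyntheticStudyConfig(overlap_fraction=1.5)
        with pytest.raises(ValueError):
            SyntheticStudyConfig(load_range=(0, 1e9))
        with pytest.raises(ValueError):
            SyntheticStudyConfig(n_cages=30, n_recipients=20)
        with pytest.raises(ValueError):
            SyntheticStudyConfig(selection={"WT": {"native_only": -1.0}})
        with pytest.raises(ValueError):
            SyntheticStudyConfig(selection={"KO_typo": {"native_only": 2.0}})

    def test_selection_factors_by_class_and_id(self):
        config = SyntheticStudyConfig(
            n_asvs_per_donor=10,
            overlap_fraction=0.2,
            selection={"WT": {"native_only": 5.0, "sh_0000": 2.0}},
        )
        s = config.selection_factors("WT")
        assert (s[s.index.str.startswith("nat_")] == 5.0).all()
        assert s["sh_0000"] == 2.0
        assert s["non_0000"] == 1.0

    def test_unknown_selection_key_is_error(self):
        config = SyntheticStudyConfig(selection={"WT": {"no_such_asv": 2.0}})
        with pytest.raises(KeyError, match="no_such_asv"):
            config.selection_factors("WT")


class TestGenerateDonor:
    def test_sigma_zero_gives_equal_abundances(self):
        config = SyntheticStudyConfig(abundance_lognormal_sigma=0.0, n_asvs_per_donor=20)
        donor = generate_donor(config, "donor_native", seed=0)
        own = donor.true_relabund[donor.true_relabund > 0]
        assert np.allclose(own, own.iloc[0])

    def test_counts_sum_to_read_depth(self):
        config = SyntheticStudyConfig()
        donor = generate_donor(config, "donor_nonnative", seed=1)
        assert donor.counts.sum() == config.read_depth

    def test_load_within_range(self):
        config = SyntheticStudyConfig(load_range=(1e8, 1e10))
        for seed in range(5):
            donor = generate_donor(config, "donor_native", seed=seed)
            assert 1e8 <= donor.donor.load <= 1e10

    def test_exclusive_blocks_disjoint(self):
        config = SyntheticStudyConfig(n_asvs_per_donor=30, overlap_fraction=0.2)
        nat = generate_donor(config, "donor_native", seed=2)
        non = generate_donor(config, "donor_nonnative", seed=3)
        nat_set = set(nat.true_relabund[nat.true_relabund > 0].index)
        non_set = set(non.true_relabund[non.true_relabund > 0].index)
        shared = nat_set & non_set
        assert all(a.startswith("sh_") for a in shared)
        assert len(shared) == config.n_shared

    def test_shannon_diversity_decreases_with_sigma(self):
        """Heavier log-normal tails concentrate abundance -> lower entropy."""
        def mean_shannon(sigma, n=30):
            config = SyntheticStudyConfig(abundance_lognormal_sigma=sigma, n_asvs_per_donor=100)
            values = []
            for seed in range(n):
                donor = generate_donor(config, "donor_native", seed=seed)
                rel = donor.true_relabund[donor.true_relabund > 0]
                values.append(-(rel * np.log(rel)).sum())
            return np.mean(values)

        assert mean_shannon(0.5) > mean_shannon(1.5) > mean_shannon(3.0)


class TestGenerateRecipients:
    def test_same_seed_identical_study(self):
        config = SyntheticStudyConfig(seed=5)
        a = generate_study(config)
        b = generate_study(config)
        assert a.table.equals(b.table)
        assert a.metadata.equals(b.metadata)
        assert a.truth.equals(b.truth)

    def test_metadata_structure(self):
        config = SyntheticStudyConfig(n_recipients=8, n_cages=2, weeks=(2, 4), genotypes=("WT", "Rag1KO"))
        study = generate_study(config)
        meta = study.metadata
        recipients = meta[meta.role == "recipient"]
        assert len(recipients) == 8 * 2 * 2  # mice x genotypes x weeks
        assert recipients.groupby("genotype")["cage_id"].nunique().tolist() == [2, 2]
        assert set(recipients.week) == {2, 4}

    def test_neutral_matches_neutral_model_distribution(self):
        """s=1, no cage effects: per-ASV recipient means match the mixture probabilities."""
        config = SyntheticStudyConfig(seed=11, n_recipients=40, n_cages=5)
        study = generate_study(config)
        nat = study.table.column(study.donor_native_id).astype(float)
        non = study.table.column(study.donor_nonnative_id).astype(float)
        w = study.mixture.weight_native
        q = (w * nat / nat.sum() + (1 - w) * non / non.sum()).to_numpy()
        recipients = study.metadata.query("role == 'recipient'")["sample_id"]
        rel = study.table.select_samples(recipients.tolist()).relative_abundance()
        observed_mean = rel.mean(axis=1).to_numpy()
        # binomial SE of the mean of 40 multinomial proportions
        se = np.sqrt(q * (1 - q) / config.read_depth / 40)
        z = (observed_mean - q) / np.maximum(se, 1e-12)
        assert np.mean(np.abs(z) < 3) > 0.98

    def test_native_selection_raises_lai(self):
        """At balanced propagule pressure (equal loads), s = 5 makes LAI positive."""
        neutral = generate_study(SyntheticStudyConfig(seed=21, load_range=(1e9, 1e9)))
        selected = generate_study(
            SyntheticStudyConfig(
                seed=21, load_range=(1e9, 1e9), selection={"WT": {"native_only": 5.0}}
            )
        )

        def mean_lai(study):
            from homesite.similarity import lai

            nat = study.table.column(study.donor_native_id)
            non = study.table.column(study.donor_nonnative_id)
            recs = study.metadata.query("role == 'recipient'")["sample_id"]
            return np.mean(
                [lai(study.table.column(r), nat, non).lai for r in recs]
            )

        assert mean_lai(selected) > mean_lai(neutral)
        assert mean_lai(selected) > 0

    def test_independent_streams_across_recipients(self):
        """Neutral recipients are uncorrelated: paired ASV count correlation ~ 0."""
        config = SyntheticStudyConfig(seed=13, n_recipients=20)
        study = generate_study(config)
        recs = study.metadata.query("role == 'recipient'")["sample_id"].tolist()
        counts = study.table.select_samples(recs).counts.astype(float)
        expected = counts.mean(axis=1, keepdims=True)
        resid = counts - expected  # remove shared mixture structure
        corrs = []
        for i in range(0, 18, 2):
            keep = (resid[:, i] != 0) | (resid[:, i + 1] != 0)
            corrs.append(stats.pearsonr(resid[keep, i], resid[keep, i + 1]).statistic)
        assert abs(np.mean(corrs)) < 0.1


class TestGenerateStudy:
    def test_files_round_trip(self, tmp_path):
        config = SyntheticStudyConfig(seed=3, n_recipients=4, n_cages=2)
        study = generate_study(config, out_dir=tmp_path)
        table = read_feature_table(tmp_path / "feature_table.tsv")
        meta = read_sample_metadata(tmp_path / "metadata.tsv")
        loads = read_donor_loads(tmp_path / "loads.tsv")
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
        assert table.equals(study.table)
        assert len(meta) == len(study.metadata)
        assert loads[study.donor_native_id].load == pytest.approx(study.mixture.native.load)
        assert set(truth.columns) >= {"asv_id", "origin", "s_WT", "expected_call"}

    def test_truth_origin_matches_classifier_at_high_depth(self):
        """With deep donor sequencing every ASV is detected; labels agree exactly."""
        config = SyntheticStudyConfig(
            seed=9, n_asvs_per_donor=40, read_depth=200_000, n_recipients=4, n_cages=2,
            abundance_lognormal_sigma=1.0,
        )
        study = generate_study(config)
        origin = classify_asv_origin(
            study.table, [study.donor_native_id], [study.donor_nonnative_id]
        )
        truth = study.truth.set_index("asv_id")["origin"]
        assert (origin.to_series().reindex(truth.index) == truth).all()

    def test_expected_call_column(self):
        config = SyntheticStudyConfig(
            genotypes=("WT", "Rag1KO"),
            selection={"WT": {"nat_0000": 5.0, "nat_0001": 0.2}},
        )
        truth = generate_study(config).truth.set_index("asv_id")
        assert truth.loc["nat_0000", "expected_call"] == "positive"
        assert truth.loc["nat_0001", "expected_call"] == "negative"
        assert truth.loc["non_0000", "expected_call"] == "none"
        assert truth.loc["nat_0000", "s_WT"] == 5.0
        assert truth.loc["nat_0000", "s_Rag1KO"] == 1.0
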