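"""The synthetic bundle generator: determinism, duplicates, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from faersignal import (
    PlantedSignal,
    SyntheticConfig,
    deduplicate,
    generate_bundle,
    inject_duplicates,
    prepare_dataset,
    ror,
    write_bundle,
)
from faersignal.synthetic import ConfigurationError, zipf_vocabulary


def _concat_demo(tables):
    return pd.concat([t.demo for t in tables], ignore_index=True)


class TestConfigValidation:
    def test_bad_probability_mass_names_the_field(self):
        with pytest.raises(ConfigurationError, match="event_vocabulary"):
            SyntheticConfig(event_vocabulary={"PT_1": 0.5, "PT_2": 0.4})

    def test_planted_pair_must_reference_vocabulary(self):
        with pytest.raises(ConfigurationError, match="planted_signals"):
            SyntheticConfig(planted_signals=[PlantedSignal("NOSUCHDRUG", "PT_001", 2.0)])

    def test_duplicate_rate_bounds(self):
        with pytest.raises(ConfigurationError, match="duplicate_rate"):
            SyntheticConfig(duplicate_rate=1.0)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SyntheticConfig(
            n_cases=10, seed=5,
            planted_signals=[PlantedSignal("TARGETDRUG", "PT_002", 3.0, age_max=18)],
        )
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestGeneration:
    def test_no_duplication_means_distinct_caseids_equal_n_cases(self):
        cfg = SyntheticConfig(n_cases=150, duplicate_rate=0.0, seed=1)
        tables, _ = generate_bundle(cfg)
        demo = _concat_demo(tables)
        assert demo["caseid"].nunique() == 150 == len(demo)

    def test_each_case_has_one_primary_suspect_and_at_least_one_pt(self):
        cfg = SyntheticConfig(n_cases=120, seed=2)
        tables, _ = generate_bundle(cfg)
        drug = pd.concat([t.drug for t in tables], ignore_index=True)
        reac = pd.concat([t.reac for t in tables], ignore_index=True)
        ps_per_report = drug[drug["role_cod"] == "PS"].groupby("primaryid").size()
        assert (ps_per_report == 1).all()
        assert set(drug["primaryid"]) <= set(ps_per_report.index)
        assert reac.groupby("primaryid").size().min() >= 1

    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        cfg = SyntheticConfig(n_cases=100, seed=9, duplicate_rate=0.1)
        for d in ("a", "b"):
            tables, _ = generate_bundle(cfg)
            write_bundle(tables, tmp_path / d)
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_pair_conservation_reac_rows_equal_pair_counts(self):
        cfg = SyntheticConfig(n_cases=200, seed=4)
        tables, _ = generate_bundle(cfg)
        reac = pd.concat([t.reac for t in tables], ignore_index=True)
        # sampling without replacement: every (report, PT) row is distinct
        assert len(reac) == len(reac.drop_duplicates())
        per_pt = reac.groupby("pt").size()
        assert per_pt.sum() == len(reac)

    def test_null_realized_counts_match_binomial_expectation(self):
        """With RR=1 everywhere and one PT per report, a planted pair's
        realized count is Binomial(n_drug_reports, p_pt)."""
        vocab = zipf_vocabulary("PT", 50)
        pairs = [
            PlantedSignal("TARGETDRUG", "PT_001", 1.0),
            PlantedSignal("TARGETDRUG", "PT_010", 1.0),
            PlantedSignal("DRUG_A", "PT_005", 1.0),
        ]
        cfg = SyntheticConfig(
            n_cases=10_000, seed=11, planted_signals=pairs,
            pts_per_report={1: 1.0}, event_vocabulary=vocab,
        )
        _, truth = generate_bundle(cfg)
        for row in truth.table.itertuples(index=False):
            p = vocab[row.pt]
            n_drug = row.expected / p
            sd = math.sqrt(n_drug * p * (1 - p))
            assert abs(row.realized - row.expected) < 4 * sd


class TestInjectDuplicates:
    def test_rate_zero_returns_input_unchanged(self):
        cfg = SyntheticConfig(n_cases=50, seed=6)
        tables, _ = generate_bundle(cfg)
        assert inject_duplicates(tables, 0.0, seed=1) is tables

    def test_floor_arithmetic_duplicates_exactly_k_cases(self):
        cfg = SyntheticConfig(n_cases=100, seed=6)
        tables, _ = generate_bundle(cfg)
        dup = inject_duplicates(tables, 0.1, seed=1)
        demo = _concat_demo(dup)
        counts = demo["caseid"].value_counts()
        assert (counts == 2).sum() == 10
        assert len(demo) == 110

    def test_duplicates_have_later_fda_dt_and_larger_primaryid(self):
        cfg = SyntheticConfig(n_cases=80, seed=6)
        tables, _ = generate_bundle(cfg)
        demo = _concat_demo(inject_duplicates(tables, 0.2, seed=2))
        for caseid, grp in demo.groupby("caseid"):
            if len(grp) == 2:
                grp = grp.sort_values("primaryid")
                assert int(grp["fda_dt"].iloc[1]) > int(grp["fda_dt"].iloc[0])
                assert int(grp["primaryid"].iloc[1]) > int(grp["primaryid"].iloc[0])

    def test_downstream_deduplication_restores_case_count(self):
        cfg = SyntheticConfig(n_cases=100, seed=6)
        tables, _ = generate_bundle(cfg)
        dup = inject_duplicates(tables, 0.1, seed=3)
        kept = deduplicate(_concat_demo(dup))
        assert len(kept) == 100


class TestSignalRecovery:
    def test_planted_rr10_ror_ci_covers_truth(self):
        """End to end: a planted RR=10 pair's ROR 95% CI should contain the
        planted relative risk in nearly all replicate bundles."""
        vocab = zipf_vocabulary("PT", 100)
        pt = "PT_050"  # rare enough that renormalization barely attenuates
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cfg = SyntheticConfig(
                n_cases=6000, seed=1000 + rep, event_vocabulary=vocab,
                planted_signals=[PlantedSignal("TARGETDRUG", pt, 10.0)],
            )
            tables, _ = generate_bundle(cfg)
            ds = prepare_dataset(tables, ["TARGETDRUG"])
            pairs = ds.pairs
            in_cohort = pairs["primaryid"].isin(ds.cohort_ids)
            a = int(((pairs["pt"] == pt) & in_cohort).sum())
            c = int(((pairs["pt"] == pt) & ~in_cohort).sum())
            b = int(in_cohort.sum()) - a
            d = int((~in_cohort).sum()) - c
            assert a >= 20  # design condition for the check
            _, lo, hi, _ = ror(a, b, c, d)
            hits += lo <= 10.0 <= hi
        assert hits >= 0.9 * n_rep
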