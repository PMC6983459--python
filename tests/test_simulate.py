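"""Synthetic-data generator: determinism, planted structure, round-trips."""

import json

import pytest

from csburden import (
    ConfigurationError,
    SimulationConfig,
    fbn1_fixture,
    simulate_cohort,
    write_fixture,
)
from csburden.coverage import harmonize, read_coverage_tsv
from csburden.pedigree import read_ped
from csburden.pipeline import _read_genotypes_tsv, _read_samples_tsv
from csburden.variants import is_novel, read_variants_tsv, read_variants_vcf


class TestConfig:
    def test_case_rate_follows_planted_odds(self):
        cfg = SimulationConfig(planted_or=4.0, carrier_rate_controls=0.005)
        p0, p1 = cfg.carrier_rate_controls, cfg.case_carrier_rate
        assert p1 / (1 - p1) == pytest.approx(4.0 * p0 / (1 - p0))

    def test_null_or_leaves_rate_unchanged(self):
        cfg = SimulationConfig(planted_or=1.0)
        assert cfg.case_carrier_rate == pytest.approx(cfg.carrier_rate_controls)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"planted_or": 0.0},
            {"planted_or": -2.0},
            {"n_cases": 0},
            {"carrier_rate_controls": 1.2},
            {"frac_imbalanced_sites": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)


class TestSimulateCohort:
    def test_same_seed_is_deterministic(self):
        cfg = SimulationConfig(seed=11, planted_or=2.0)
        d1, d2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert [v.variant_id for v in d1.variants] == [
            v.variant_id for v in d2.variants
        ]
        assert d1.genotypes == d2.genotypes
        assert d1.coverage == d2.coverage
        assert d1.truth == d2.truth

    def test_exact_imbalanced_site_count(self):
        cfg = SimulationConfig(seed=3, n_sites=500, frac_imbalanced_sites=0.048)
        ds = simulate_cohort(cfg)
        result = harmonize(ds.coverage)
        assert len(result.excluded) == round(0.048 * 500)

    def test_variants_avoid_pruned_sites(self):
        cfg = SimulationConfig(seed=5, planted_or=4.0)
        ds = simulate_cohort(cfg)
        excluded = harmonize(ds.coverage).excluded
        assert all(v.site not in excluded for v in ds.variants)

    def test_carriers_are_singletons_by_default(self):
        ds = simulate_cohort(SimulationConfig(seed=7))
        carried = [vid for s in ds.genotypes.values() for vid in s]
        assert len(carried) == len(set(carried))

    def test_recurrence_knob_creates_doubletons(self):
        cfg = SimulationConfig(seed=9, planted_or=6.0, n_recurrent_case_variants=1)
        ds = simulate_cohort(cfg)
        from collections import Counter

        multiplicity = Counter(
            vid for s in ds.genotypes.values() for vid in s
        )
        assert 2 in multiplicity.values()

    def test_leak_rate_respected_within_binomial_error(self):
        # pool variants over several seeds; leaked fraction ~ Binomial(n, rate)
        rate = 0.3
        leaked = total = 0
        for seed in range(12):
            ds = simulate_cohort(
                SimulationConfig(seed=seed, novelty_leak_rate=rate, planted_or=3.0)
            )
            leaked += sum(1 for v in ds.variants if v.freq)
            total += len(ds.variants)
        phat = leaked / total
        se = (rate * (1 - rate) / total) ** 0.5
        assert abs(phat - rate) < 4 * se

    def test_leaked_variants_fail_novelty(self):
        ds = simulate_cohort(SimulationConfig(seed=13, novelty_leak_rate=1.0))
        assert all(not is_novel(v) for v in ds.variants)


class TestWriteFixture:
    def test_manifest_and_round_trip(self, tmp_path):
        cfg = SimulationConfig(seed=21, planted_or=3.0, novelty_leak_rate=0.3)
        ds = simulate_cohort(cfg)
        manifest = write_fixture(ds, tmp_path)
        assert len(manifest) >= 5
        assert set(manifest) <= {p.name for p in tmp_path.iterdir()}

        # flat TSV round-trip preserves the variant records
        back = read_variants_tsv(tmp_path / "variants.tsv")
        assert [v.variant_id for v in back] == [v.variant_id for v in ds.variants]
        for w, v in zip(back, ds.variants):
            assert set(w.freq) == set(v.freq)
            for resource, af in v.freq.items():
                assert w.freq[resource] == pytest.approx(af, rel=1e-9)

        # VCF round-trip preserves annotations and carrier sets
        vcf_variants, vcf_genotypes = read_variants_vcf(tmp_path / "cohort.vcf")
        assert {v.variant_id for v in vcf_variants} == {
            v.variant_id for v in ds.variants
        }
        by_id = {v.variant_id: v for v in vcf_variants}
        for v in ds.variants:
            w = by_id[v.variant_id]
            assert w.consequence == v.consequence
            if v.cadd is not None:
                assert w.cadd == pytest.approx(v.cadd, rel=1e-5)
        assert {s: c for s, c in vcf_genotypes.items() if c} == {
            s: c for s, c in ds.genotypes.items() if c
        }

        # coverage, samples and pedigree reload cleanly
        assert read_coverage_tsv(tmp_path / "coverage.tsv") == ds.coverage
        cases, controls = _read_samples_tsv(tmp_path / "samples.tsv")
        assert (cases, controls) == (ds.cases, ds.controls)
        (ped,) = read_ped(tmp_path / "family.ped")
        assert [m.member_id for m in ped.members] == [
            m.member_id for m in ds.pedigrees[0].members
        ]
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["planted_or"] == 3.0

    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=33)
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        m1 = write_fixture(simulate_cohort(cfg), tmp_path / "a")
        m2 = write_fixture(simulate_cohort(cfg), tmp_path / "b")
        assert m1 == m2  # SHA-256 manifests match byte for byte

    def test_missing_directory_is_error(self, tmp_path):
        ds = simulate_cohort(SimulationConfig(seed=1))
        from csburden import InputFormatError

        with pytest.raises(InputFormatError):
            write_fixture(ds, tmp_path / "does-not-exist")


class TestReferenceFixture:
    def test_inventory_matches_published_margins(self, reference_dataset):
        ds = reference_dataset
        assert len(ds.cases) == 574
        assert len(ds.controls) == 828
        carriers_case = sum(1 for s in ds.cases if ds.genotypes[s])
        carriers_control = sum(1 for s in ds.controls if ds.genotypes[s])
        assert (carriers_case, carriers_control) == (16, 14)
        # 29 distinct records; the recurrent missense yields 30 alleles
        assert len(ds.variants) == 29

    def test_recurrent_variant_in_exactly_two_cases(self, reference_dataset):
        ds = reference_dataset
        vid = ds.truth["recurrent_variant"]
        carriers = sorted(s for s, c in ds.genotypes.items() if vid in c)
        assert carriers == ["XH579", "XH73"]
        assert set(carriers) <= set(ds.cases)

    def test_all_fixture_variants_are_novel(self, reference_dataset):
        assert all(is_novel(v) for v in reference_dataset.variants)

    def test_deterministic(self):
        a, b = fbn1_fixture(), fbn1_fixture()
        assert [v.variant_id for v in a.variants] == [
            v.variant_id for v in b.variants
        ]
        assert a.genotypes == b.genotypes
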