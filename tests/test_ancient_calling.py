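"""Damage-aware presence calling and damage-profile estimation."""

import numpy as np
import pandas as pd
import pytest

import paleopv as pv
from paleopv.ancient_calling import (ReadObservation, PileupSite,
                                     call_variant_presence, damage_suspect,
                                     sites_from_pileup)


def obs(base, baseq=30, dist5=10, dist3=30, strand="+"):
    return ReadObservation(base=base, baseq=baseq, dist5=dist5, dist3=dist3,
                           strand=strand)


def variant(ref="C", alt="T", pos=100):
    return pv.Variant("chr1", pos, ref, alt, "BRCA1", "pathogenic", 3)


class TestDamageSuspect:
    def test_terminal_ct_is_suspect(self):
        assert damage_suspect(obs("T", dist5=0), "C", "T", k=3)
        assert damage_suspect(obs("T", dist5=2), "C", "T", k=3)
        assert not damage_suspect(obs("T", dist5=3), "C", "T", k=3)

    def test_terminal_ga_uses_three_prime_end(self):
        assert damage_suspect(obs("A", dist5=40, dist3=1), "G", "A", k=3)
        assert not damage_suspect(obs("A", dist5=1, dist3=40), "G", "A", k=3)

    def test_non_deamination_classes_never_suspect(self):
        for ref, alt in (("A", "G"), ("T", "C"), ("C", "A"), ("G", "T")):
            assert not damage_suspect(obs(alt, dist5=0, dist3=0), ref, alt, k=10)

    def test_simulated_terminal_rate_matches_planted_d0(self):
        """Among 5'-terminal C sites, the observed C->T fraction must match
        d0 within binomial error."""
        rng = np.random.default_rng(23)
        seq = "C" * 500
        damage = pv.DamageModel(d0=0.3, lam=0.5, k=3)
        pileup = pv.simulate_ancient_reads(
            seq, {}, coverage=40, read_len=50, damage=damage, seed=23,
            sites=list(range(1, 501)))
        term = pileup[pileup["dist5"] == 0]
        n = len(term)
        rate = (term["base"] == "T").mean()
        sigma = np.sqrt(0.3 * 0.7 / n)
        assert abs(rate - 0.3) < 4 * sigma


class TestCallPresence:
    def test_empty_site_is_no_data(self):
        site = PileupSite("S1", "chr1", 100, "C", ())
        call = call_variant_presence(site, variant())
        assert call.status == "no_data" and call.depth == 0

    def test_all_terminal_ct_support_is_damage_only(self):
        """Three alt reads all within the k=3 window: the call must be absent
        with the damage_only flag (all support is suspect by definition)."""
        reads = tuple(obs("T", dist5=d) for d in (0, 1, 2))
        site = PileupSite("S1", "chr1", 100, "C", reads)
        call = call_variant_presence(site, variant(), k=3)
        assert call.status == "absent"
        assert call.damage_only
        assert call.alt_total == 3 and call.alt_clean == 0

    def test_single_low_quality_read_calls_non_ct_variant(self):
        site = PileupSite("S1", "chr1", 100, "A",
                          (obs("G", baseq=1, dist5=0, dist3=0),))
        call = call_variant_presence(site, variant(ref="A", alt="G"),
                                     min_baseq=1)
        assert call.status == "present"
        assert call.low_depth

    def test_baseq_filter_removes_observations(self):
        reads = (obs("T", baseq=0, dist5=20), obs("C", baseq=30, dist5=20))
        site = PileupSite("S1", "chr1", 100, "C", reads)
        call = call_variant_presence(site, variant(), min_baseq=1)
        assert call.depth == 1 and call.alt_total == 0

    def test_coordinate_mismatch_is_contract_error(self):
        site = PileupSite("S1", "chr1", 101, "C", ())
        with pytest.raises(pv.ContractError):
            call_variant_presence(site, variant(pos=100))

    def test_k_toggle_only_affects_deamination_classes(self):
        """Metamorphic: toggling k between 0 and 10 never changes calls for
        variants outside the C->T / G->A classes."""
        rng = np.random.default_rng(29)
        for ref, alt in (("A", "G"), ("T", "G"), ("C", "G"), ("A", "C")):
            reads = tuple(
                obs(alt if rng.random() < 0.5 else ref,
                    dist5=int(rng.integers(0, 50)),
                    dist3=int(rng.integers(0, 50)))
                for _ in range(10))
            site = PileupSite("S1", "chr1", 100, ref, reads)
            calls = [call_variant_presence(site, variant(ref=ref, alt=alt), k=k)
                     for k in (0, 10)]
            assert calls[0].status == calls[1].status
            assert calls[0].alt_clean == calls[1].alt_clean


class TestScanSamples:
    def _setup(self, seed=31, d0=0.0, seq_error=0.0, coverage=15,
               n_samples=4, n_variants=6):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        catalog, _, _ = pv.plant_variants({"human": seq}, n_variants, seed=seed)
        samples = [pv.AncientSample(f"S{i}", date_bp=500.0 * (i + 1),
                                    location="Simland")
                   for i in range(n_samples)]
        labels = [v.label for v in catalog]
        truth = {s.sample_id: [labels[j] for j in range(len(labels))
                               if rng.random() < 0.4]
                 for s in samples}
        damage = pv.DamageModel(d0=d0, lam=0.5, k=3)
        pileup, _ = pv.simulate_cohort(seq, catalog, truth, samples, coverage,
                                       50, damage, seq_error=seq_error,
                                       seed=seed)
        meta = {s.sample_id: s for s in samples}
        return catalog, pileup, meta, truth

    def test_clean_simulation_recovers_truth_exactly(self):
        """With no damage and no sequencing error, the carrier table must
        reproduce the planted truth."""
        catalog, pileup, meta, truth = self._setup()
        calls = pv.scan_samples(catalog, pileup, meta)
        present = calls[calls["status"] == "present"]
        got = {sid: set(grp["variant"])
               for sid, grp in present.groupby("sample_id")}
        expected = {sid: set(v) for sid, v in truth.items() if v}
        assert got == expected

    def test_zero_coverage_sites_are_no_data(self):
        site = PileupSite("S1", "chr1", 100, "C", ())
        assert call_variant_presence(site, variant()).status == "no_data"

    def test_orphan_sample_id_raises(self):
        catalog, pileup, meta, _ = self._setup()
        del meta["S0"]
        with pytest.raises(pv.ValidationError, match="S0"):
            pv.scan_samples(catalog, pileup, meta)

    def test_metadata_joined(self):
        catalog, pileup, meta, _ = self._setup()
        calls = pv.scan_samples(catalog, pileup, meta)
        assert set(calls["group"]) == {"ancient_human"}
        s0 = calls[calls["sample_id"] == "S0"]
        assert (s0["date_bp"] == 500.0).all()

    def test_sensitivity_nondecreasing_in_coverage(self):
        """Detection of a planted heterozygous carrier cannot get worse as
        coverage grows (averaged over seeds)."""
        rates = []
        for coverage in (1, 2, 5, 10):
            hits = total = 0
            for seed in range(40, 52):
                catalog, pileup, meta, truth = self._setup(
                    seed=seed, coverage=coverage, n_samples=2, n_variants=4)
                calls = pv.scan_samples(catalog, pileup, meta)
                present = calls[calls["status"] == "present"]
                got = {sid: set(grp["variant"])
                       for sid, grp in present.groupby("sample_id")}
                for sid, vars_ in truth.items():
                    for label in vars_:
                        total += 1
                        hits += label in got.get(sid, set())
            rates.append(hits / max(total, 1))
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestDamageEstimation:
    def _pileup(self, d0, lam=0.5, seed=53, coverage=40, length=1500,
                seq_error=0.0, c_sites_only=False):
        rng = np.random.default_rng(seed)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        damage = pv.DamageModel(d0=d0, lam=lam, k=3)
        sites = ([i + 1 for i, b in enumerate(seq) if b == "C"]
                 if c_sites_only else list(range(1, length + 1)))
        return pv.simulate_ancient_reads(
            seq, {}, coverage=coverage, read_len=60, damage=damage, seed=seed,
            seq_error=seq_error, sites=sites)

    def test_parameter_recovery(self):
        """50k C-reference observations in the fit window recover d0 within
        +/-0.05 and lam within +/-0.15."""
        pileup = self._pileup(d0=0.3, coverage=220, length=4000,
                              c_sites_only=True)
        in_window = pileup[(pileup["ref"] == "C") & (pileup["dist5"] < 15)]
        assert len(in_window) >= 50_000
        model = pv.estimate_damage_profile(pileup, max_pos=15)
        assert abs(model.d0 - 0.3) <= 0.05
        assert abs(model.lam - 0.5) <= 0.15

    def test_null_recovery_without_damage(self):
        """With d0 = 0 the only C->T mismatches come from sequencing error,
        so the fitted terminal rate must stay at the error floor."""
        pileup = self._pileup(d0=0.0, seq_error=0.01)
        model = pv.estimate_damage_profile(pileup, max_pos=15)
        # per-base C->T error is seq_error / 3; allow generous binomial slack
        assert model.d0 <= 0.01 + 0.01

    def test_null_recovery_is_error_when_unfittable(self):
        """Zero mismatches everywhere cannot support a two-parameter fit."""
        pileup = pd.DataFrame({
            "sample_id": "S1", "chrom": "chr1", "pos": range(1, 3001),
            "ref": "C", "base": "C", "baseq": 30,
            "dist5": np.arange(3000) % 20, "dist3": 10, "strand": "+",
            "read_id": "r"})
        with pytest.raises(pv.ValidationError):
            pv.estimate_damage_profile(pileup, max_pos=15)

    def test_single_position_data_is_error(self):
        pileup = pd.DataFrame({
            "sample_id": "S1", "chrom": "chr1", "pos": 1, "ref": "C",
            "base": ["T"] * 600 + ["C"] * 1400, "baseq": 30, "dist5": 0,
            "dist3": 10, "strand": "+", "read_id": "r"})
        with pytest.raises(pv.ValidationError):
            pv.estimate_damage_profile(pileup, max_pos=15)

    def test_no_c_reference_observations_is_error(self):
        pileup = pd.DataFrame({
            "sample_id": "S1", "chrom": "chr1", "pos": 1, "ref": "A",
            "base": "A", "baseq": 30, "dist5": [0, 1], "dist3": 10,
            "strand": "+", "read_id": "r"})
        with pytest.raises(pv.ValidationError):
            pv.estimate_damage_profile(pileup, max_pos=15)


class TestPileupIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(59)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        damage = pv.DamageModel(d0=0.1, lam=0.4, k=3)
        pileup = pv.simulate_ancient_reads(seq, {}, coverage=5, read_len=40,
                                           damage=damage, seed=59,
                                           sites=[10, 100, 200])
        path = tmp_path / "pile.tsv"
        pv.write_pileup_tsv(pileup, path)
        back = pv.read_pileup_tsv(path)
        pd.testing.assert_frame_equal(pileup, back)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"sample_id": ["S1"], "chrom": ["chr1"]}).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(pv.SchemaError):
            pv.read_pileup_tsv(path)

    def test_sites_grouping(self):
        df = pd.DataFrame({
            "sample_id": ["S1"] * 3 + ["S2"],
            "chrom": "chr1", "pos": [5, 5, 9, 5], "ref": "C",
            "base": ["T", "C", "A", "C"], "baseq": 30, "dist5": [0, 5, 9, 3],
            "dist3": [39, 34, 30, 36], "strand": "+",
            "read_id": ["a", "b", "c", "d"]})
        sites = sites_from_pileup(df)
        assert sites[("S1", "chr1", 5)].depth == 2
        assert sites[("S2", "chr1", 5)].depth == 1

    def test_sam_reader_produces_observations(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:chr1\tLN:100\n"
            "r1\t0\tchr1\t10\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
            "r2\t16\tchr1\t12\t60\t10M\t*\t0\t0\tGTACGTACGT\tIIIIIIIIII\n")
        from paleopv.ancient_calling import sam_to_pileup
        df = sam_to_pileup(sam, [("chr1", 12)], "S1")
        assert len(df) == 2
        fwd = df[df["read_id"] == "r1"].iloc[0]
        rev = df[df["read_id"] == "r2"].iloc[0]
        assert fwd["base"] == "G" and fwd["dist5"] == 2
        assert rev["base"] == "G" and rev["dist5"] == 9 and rev["strand"] == "-"
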