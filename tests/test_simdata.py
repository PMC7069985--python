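"""Synthetic-study generator: amplicons, cohorts, reads, melt curves."""

import numpy as np
import pytest
from scipy import stats

from hapmeth import simdata
from hapmeth.core import AmpliconReference, HaplotypeCatalog, Marker
from hapmeth.simdata import (
    MeltParams,
    SimParams,
    build_sites,
    build_truth,
    make_amplicon,
    make_cohort,
    simulate_melt,
    simulate_reads,
)


def _mono_catalog():
    return HaplotypeCatalog([], {"h1": ()}, "h1")


class TestMakeAmplicon:
    def test_marker_plan_and_catalog(self):
        rng = np.random.default_rng(3)
        amp, sites, cat = make_amplicon(
            1000, 0.02, [("SNP", 2), ("CpG-SNP", 4), ("indel", 1)], rng
        )
        assert len(amp.sequence) == 1000
        assert len(cat.markers) == 7
        assert 2 <= len(cat.haplotypes) <= 3
        assert cat.risk_haplotype in cat.haplotypes
        # every C on both strands is catalogued
        plus = {s.coord for s in sites if s.strand == "+"}
        for i, b in enumerate(amp.sequence):
            if b == "C":
                assert amp.start_coord + i in plus

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            make_amplicon(100, 0.02, [], np.random.default_rng(0))

    def test_collision_error_names_positions(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="collision"):
            # more markers than a 200 bp amplicon can space out
            make_amplicon(200, 0.01, [("SNP", 40)], rng)

    def test_palindromic_cpg_sites(self):
        amp = AmpliconReference("t", "chr1", 1, "ACGT")
        sites = build_sites(amp, _mono_catalog())
        by = {(s.coord, s.strand): s for s in sites}
        assert by[(2, "+")].context == "CpG"
        assert by[(3, "-")].context == "CpG"
        assert len(sites) == 2

    def test_cpg_snp_alt_removes_cytosine(self):
        amp = AmpliconReference("t", "chr1", 1, "AACGTT")
        cat = HaplotypeCatalog(
            [Marker("m", 3, "C", "T")], {"keep": ("C",), "lose": ("T",)}, "lose"
        )
        sites = build_sites(amp, cat)
        site = next(s for s in sites if s.coord == 3 and s.strand == "+")
        assert site.context_by_haplotype == {"keep": "CpG", "lose": "absent"}
        # C/T at the cytosine itself confounds conversion on OT: maskable
        assert site.maskable_by_haplotype["keep"] is True


class TestMakeCohort:
    def test_hwe_heterozygote_fraction(self):
        rng = np.random.default_rng(1)
        subjects = make_cohort(500, 500, {"a": 0.5, "b": 0.5}, rng=rng)
        het = np.mean([s.genotype[0] != s.genotype[1] for s in subjects])
        # expected 2pq = 0.5; +/- ~3 binomial sd at n=1000
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / 1000)

    def test_group_cognitive_t_difference(self):
        rng = np.random.default_rng(2)
        subjects = make_cohort(3000, 3000, {"a": 1.0}, rng=rng)
        cases = [s.cognitive_T for s in subjects if s.group == "case"]
        controls = [s.cognitive_T for s in subjects if s.group == "control"]
        assert np.mean(controls) - np.mean(cases) == pytest.approx(10.97, abs=0.5)

    def test_control_only_cohort(self):
        subjects = make_cohort(0, 10, {"a": 1.0}, rng=np.random.default_rng(0))
        assert len(subjects) == 10
        assert all(s.group == "control" for s in subjects)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(0, 0, {"a": 1.0})

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            make_cohort(5, 5, {"a": 0.6, "b": 0.6})


def _tiny_design(truth_value: float):
    amp = AmpliconReference("t", "chr1", 1, "GATTCGATTACA" * 10)
    cat = _mono_catalog()
    sites = build_sites(amp, cat)
    meth = {("h1", s.site_id): truth_value for s in sites}
    truth = simdata.TruthTable(meth=meth)
    subjects = make_cohort(1, 0, {"h1": 1.0}, rng=np.random.default_rng(0))
    return amp, sites, cat, truth, subjects


class TestSimulateReads:
    def test_fully_methylated_site_never_converts(self):
        amp, sites, cat, truth, subjects = _tiny_design(1.0)
        params = SimParams(sequencing_error_rate=0.0, duplication_rate=0.0,
                           molecule_failure_rate=0.0, reads_per_subject=20)
        reads, tt, _ = simulate_reads(
            subjects, amp, sites, cat, truth, params, np.random.default_rng(0)
        )
        for r in reads:
            insert = r.sequence[8:-8]
            assert insert == amp.sequence  # all cytosines retained

    def test_unmethylated_fully_converted_at_perfect_efficiency(self):
        amp, sites, cat, truth, subjects = _tiny_design(0.0)
        params = SimParams(conversion_efficiency=1.0, molecule_failure_rate=0.0,
                           sequencing_error_rate=0.0, duplication_rate=0.0,
                           reads_per_subject=20)
        reads, tt, _ = simulate_reads(
            subjects, amp, sites, cat, truth, params, np.random.default_rng(0)
        )
        for r, mol in zip(reads, tt.molecules):
            insert = r.sequence[8:-8]
            if mol.bs_strand == "OT":
                assert "C" not in insert
                assert insert == amp.sequence.replace("C", "T")
            else:
                assert "G" not in insert
                assert insert == amp.sequence.replace("G", "A")

    def test_conservation_reads_equal_molecules(self, clean_sim):
        _, reads, truth, _ = clean_sim
        assert len(reads) == len(truth.molecules)
        ids = {m.read_id for m in truth.molecules}
        assert all(r.read_id in ids for r in reads)

    def test_determinism_byte_identical(self):
        amp, sites, cat, truth, subjects = _tiny_design(0.5)
        params = SimParams(rng_seed=42, reads_per_subject=15)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(params.rng_seed)
            reads, tt, _ = simulate_reads(subjects, amp, sites, cat, truth, params, rng)
            out.append([(r.read_id, r.sequence) for r in reads])
        assert out[0] == out[1]

    def test_unknown_haplotype_rejected(self):
        amp, sites, cat, truth, subjects = _tiny_design(0.5)
        bad = simdata.TruthTable(meth={})
        with pytest.raises(ValueError):
            simulate_reads(subjects, amp, sites, cat, bad, SimParams(),
                           np.random.default_rng(0))

    def test_truth_recovery_under_clean_conditions(self, fr_design):
        """With error/failure/duplication at 0 and efficiency 1, empirical
        unconverted fractions match true M within the 95% binomial CI."""
        amp, sites, catalog, truth = fr_design
        rng = np.random.default_rng(9)
        subjects = make_cohort(10, 10, {"TIGACAI": 0.5, "ADAGAGD": 0.5}, rng=rng)
        params = SimParams(conversion_efficiency=1.0, molecule_failure_rate=0.0,
                           sequencing_error_rate=0.0, duplication_rate=0.0,
                           reads_per_subject=30)
        reads, tt, _ = simulate_reads(subjects, amp, sites, catalog, truth, params, rng)
        counts = {}
        for mol in tt.molecules:
            for site_id, methylated in mol.states.items():
                k = (mol.haplotype, site_id)
                n, u = counts.get(k, (0, 0))
                counts[k] = (n + 1, u + int(methylated))
        checked = 0
        for (hap, site_id), (n, u) in counts.items():
            if n < 50:
                continue
            p = truth.meth[(hap, site_id)]
            lo, hi = stats.binom.interval(0.999, n, p)
            assert lo <= u <= hi, (hap, site_id, u, n, p)
            checked += 1
        assert checked > 50

    def test_strand_symmetry_of_palindromic_cpg(self, fr_design):
        """OT-only and OB-only reads recover equal M at a symmetric CpG."""
        amp, sites, catalog, truth = fr_design
        rng = np.random.default_rng(21)
        subjects = make_cohort(6, 6, {"ADAGAGD": 1.0}, rng=rng)
        params = SimParams(conversion_efficiency=1.0, molecule_failure_rate=0.0,
                           sequencing_error_rate=0.0, duplication_rate=0.0,
                           reads_per_subject=60)
        _, tt, _ = simulate_reads(subjects, amp, sites, catalog, truth, params, rng)
        plus = next(s for s in sites if s.coord == 104_060_054 and s.strand == "+")
        minus = next(s for s in sites if s.coord == 104_060_055 and s.strand == "-")
        rates = {}
        for site in (plus, minus):
            st = [m.states[site.site_id] for m in tt.molecules if site.site_id in m.states]
            rates[site.strand] = np.mean(st)
        assert abs(rates["+"] - rates["-"]) < 0.12  # sampling error at ~360x


class TestSimulateMelt:
    def test_zero_shift_matches_unmethylated_standard(self):
        p = MeltParams(delta_tm=0.0)
        a = simulate_melt([0.0], p)
        b = simulate_melt([1.0], p)
        assert np.allclose(a.fluorescence, b.fluorescence)

    def test_symmetric_standards_cross_nowhere_max_gap_midway(self):
        p = MeltParams(tm_unmethylated=75.0, delta_tm=5.0, slope=1.5)
        un = simulate_melt([0.0], p)
        me = simulate_melt([1.0], p)
        gap = un.fluorescence - me.fluorescence
        assert np.all(gap <= 1e-12)  # unmethylated melts first, curves never cross
        t_star = un.temperatures[np.argmax(np.abs(gap))]
        assert t_star == pytest.approx(77.5, abs=p.t_step)

    def test_heterozygote_between_standards(self):
        p = MeltParams()
        un = simulate_melt([0.0], p)
        me = simulate_melt([1.0], p)
        het = simulate_melt([0.0, 1.0], p)
        # methylated template melts last, so its curve is the upper envelope
        assert np.all(het.fluorescence >= un.fluorescence - 1e-12)
        assert np.all(het.fluorescence <= me.fluorescence + 1e-12)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            simulate_melt([0.5], MeltParams(t_min=70, t_max=70))
        with pytest.raises(ValueError):
            simulate_melt([0.5], MeltParams(t_min=50))

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            simulate_melt([0.5], MeltParams(noise_sd=0.01))


def test_sim_params_validation():
    with pytest.raises(ValueError):
        SimParams(conversion_efficiency=1.2)
    with pytest.raises(ValueError):
        SimParams(reads_per_subject=0)


def test_packaged_truth_profile_defaults(fr_design):
    amp, sites, catalog, truth = fr_design
    by = {(s.coord, s.strand): s for s in sites}
    # pinned profile values
    assert truth.meth[("TIGACAI", by[(104_060_054, "+")].site_id)] == 0.87
    assert truth.meth[("TIGACAI", by[(104_060_367, "+")].site_id)] == 0.01
    assert truth.meth[("TIGACAI", by[(104_060_378, "+")].site_id)] == 0.98
    # unlisted sites fall back to context defaults
    unpinned_cpg = next(
        s for s in sites
        if s.strand == "+" and s.context == "CpG"
        and s.coord not in {int(c) for c in simdata.load_asm_truth_profile()["coord"]}
        and s.context_by_haplotype["ADAGAGD"] == "CpG"
    )
    assert truth.meth[("ADAGAGD", unpinned_cpg.site_id)] == simdata.DEFAULT_CPG_TRUTH
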