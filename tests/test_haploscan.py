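import numpy as np
import pytest

from haplosweep import haploscan as hs
from haplosweep.types import DomainError, HaplotypeForm, SelectionSignal

from conftest import make_panel, random_panel
from oracles import longest_window_through, maximal_forms


def form_with(cm, snps, start=1, chrom="1"):
    """A free-standing form with prescribed length metrics."""
    sites = tuple((start + i, 0) for i in range(snps))
    return HaplotypeForm(
        chromosome=chrom,
        sites=sites,
        span_start_bp=start,
        span_end_bp=start + max(snps - 1, 0) + 1,
        genetic_length_cm=cm,
        snp_count=snps,
        carrier_frequency=0.5,
    )


class TestGrowLongestForm:
    def test_identical_chromosomes_grow_across_the_whole_panel(self):
        panel = make_panel(np.tile([0, 1, 1, 0, 1], (6, 1)))
        form = hs.grow_longest_form(panel, 2, 1, f=0.95)
        assert form.snp_count == 5
        assert form.carrier_frequency == 1.0
        assert form.sites == ((0, 0), (1, 1), (2, 1), (3, 0), (4, 1))

    def test_low_frequency_seed_returns_none(self):
        alleles = np.zeros((10, 4), dtype=np.int8)
        alleles[0, 1] = 1  # allele 1 at 10%
        panel = make_panel(alleles)
        assert hs.grow_longest_form(panel, 1, 1, f=0.25) is None

    def test_seed_out_of_range_raises(self, toy_panel):
        with pytest.raises(IndexError):
            hs.grow_longest_form(toy_panel, 99, 0, f=0.25)

    def test_toy_panel_matches_enumeration_oracle(self, toy_panel):
        # the three identical rows support the full-width form at f=0.25
        form = hs.grow_longest_form(toy_panel, 0, 0, f=0.25)
        assert form.sites == ((0, 0), (1, 1), (2, 1), (3, 0), (4, 1), (5, 0))
        assert form.carrier_frequency == pytest.approx(3 / 8)
        want = longest_window_through(toy_panel.alleles, 0.25, 0, 0)
        assert set(want) <= set(form.sites)

    @pytest.mark.parametrize("seed", range(8))
    def test_grow_matches_longest_window_oracle(self, seed):
        rng = np.random.default_rng(700 + seed)
        panel = random_panel(rng)
        f = float(rng.choice([0.1, 0.25, 0.4]))
        for snp in range(panel.n_snps):
            for allele in (0, 1):
                if panel.allele_code_frequency(snp, allele) < f:
                    continue
                got = hs.grow_longest_form(panel, snp, allele, f)
                want = longest_window_through(
                    panel.alleles, f, snp, allele
                )
                assert got is not None and want is not None
                assert len(got.sites) == len(want)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotonicity_in_frequency(self, seed):
        """Raising the bin can only shrink the achievable form."""
        rng = np.random.default_rng(900 + seed)
        panel = random_panel(rng, n_chrom=12, n_snps=10)
        for snp in (0, panel.n_snps // 2):
            for allele in (0, 1):
                prev = None
                for f in (0.1, 0.25, 0.4, 0.6):
                    form = hs.grow_longest_form(panel, snp, allele, f)
                    if form is None:
                        break
                    if prev is not None:
                        assert form.snp_count <= prev.snp_count
                        assert (
                            form.genetic_length_cm
                            <= prev.genetic_length_cm + 1e-12
                        )
                    prev = form

    def test_skip_allowance_bridges_a_disrupted_site(self):
        base = np.tile([0, 1, 1, 0, 1], (8, 1)).astype(np.int8)
        # SNP 2 disagrees on half the rows: joint carriers drop below 0.75
        base[:4, 2] = 0
        panel = make_panel(base)
        strict = hs.grow_longest_form(panel, 0, 0, f=0.75, skip_allowance=0)
        bridged = hs.grow_longest_form(panel, 0, 0, f=0.75, skip_allowance=1)
        assert strict.snp_count == 2
        assert bridged.snp_count == 4  # SNP 2 skipped, not part of the form
        assert 2 not in [i for i, _ in bridged.sites]


class TestScanPopulation:
    @pytest.mark.parametrize("seed", range(10))
    def test_candidate_set_equals_oracle_maximal_windows(self, seed):
        rng = np.random.default_rng(1000 + seed)
        panel = random_panel(rng)
        for f in (0.1, 0.25, 0.4, 0.6):
            got = {fo.sites for fo in hs.scan_population(panel, bins=[f])[f]}
            assert got == maximal_forms(panel.alleles, f)

    def test_scan_is_deterministic(self, toy_panel):
        a = hs.scan_population(toy_panel, bins=[0.25, 0.5])
        b = hs.scan_population(toy_panel, bins=[0.25, 0.5])
        assert {f: [x.sites for x in v] for f, v in a.items()} == {
            f: [x.sites for x in v] for f, v in b.items()
        }

    def test_unrelated_haplotypes_give_short_high_bin_forms(self):
        rng = np.random.default_rng(5)
        panel = random_panel(rng, n_chrom=16, n_snps=12)
        forms = hs.scan_population(panel, bins=[0.5])[0.5]
        assert forms and max(f.snp_count for f in forms) <= 4

    def test_grid_has_19_bins(self):
        assert len(hs.FREQUENCY_GRID) == 19
        assert hs.FREQUENCY_GRID[0] == 0.05 and hs.FREQUENCY_GRID[-1] == 0.95
        steps = np.diff(hs.FREQUENCY_GRID)
        assert np.allclose(steps, 0.05)


class TestEmpiricalPvaluesAndScore:
    def test_unique_double_maximum_among_100(self):
        forms = [form_with(cm=0.1, snps=2, start=10 * i) for i in range(99)]
        target = form_with(cm=5.0, snps=9, start=2000)
        p_cm, p_snp = hs.empirical_pvalues(target, forms + [target])
        assert p_cm == p_snp == pytest.approx(0.01)

    def test_global_minimum_has_pvalue_one(self):
        forms = [form_with(cm=1.0 + i, snps=3 + i, start=50 * i) for i in range(5)]
        target = form_with(cm=0.5, snps=2, start=999)
        p_cm, p_snp = hs.empirical_pvalues(target, forms + [target])
        assert p_cm == p_snp == 1.0

    def test_ties_count_toward_the_numerator(self):
        lengths = [0.5, 1.0, 2.0, 2.0, 3.0]
        forms = [
            form_with(cm=c, snps=2, start=100 * i)
            for i, c in enumerate(lengths)
        ]
        target = forms[2]  # 2.0 cM
        p_cm, _ = hs.empirical_pvalues(target, forms)
        assert p_cm == pytest.approx(3 / 5)

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(DomainError):
            hs.empirical_pvalues(form_with(1.0, 2), [])

    def test_score_examples(self):
        assert hs.haplops_score(1.0, 1.0, 100) == (100.0, False)
        score, sig = hs.haplops_score(0.01, 0.02, 100)
        assert score == pytest.approx(0.02) and sig

    @pytest.mark.parametrize("n,expect_sig", [(10, False), (20, False), (21, True), (100, True)])
    def test_unique_double_maximum_significant_iff_more_than_20_candidates(
        self, n, expect_sig
    ):
        score, sig = hs.haplops_score(1 / n, 1 / n, n)
        assert score == pytest.approx(1 / n)
        assert sig is expect_sig

    def test_score_invariant_under_candidate_permutation(self, rng):
        forms = [
            form_with(cm=float(rng.uniform(0, 3)), snps=int(rng.integers(2, 9)),
                      start=100 * i)
            for i in range(30)
        ]
        target = forms[7]
        p1 = hs.empirical_pvalues(target, forms)
        shuffled = list(forms)
        rng.shuffle(shuffled)
        assert hs.empirical_pvalues(target, shuffled) == p1


def signal(pop, chrom, start, end, fbin, cm, score=0.01):
    form = HaplotypeForm(
        chromosome=chrom,
        sites=((0, 0), (1, 1)),
        span_start_bp=start,
        span_end_bp=end,
        genetic_length_cm=cm,
        snp_count=2,
        carrier_frequency=fbin,
    )
    return SelectionSignal(
        population=pop,
        chromosome=chrom,
        start_bp=start,
        end_bp=end,
        form=form,
        frequency_bin=fbin,
        n_f=100,
        score=score,
        p_cm=0.001,
        p_snp=0.1,
    )


class TestCollapse:
    def test_same_region_reported_only_at_highest_bin(self):
        sigs = [
            signal("CHB", "1", 100, 900, fbin, cm=1.0)
            for fbin in (0.20, 0.30, 0.40)
        ]
        out = hs.collapse_to_highest_frequency(sigs)
        assert len(out) == 1 and out[0].frequency_bin == 0.40

    def test_disjoint_regions_both_reported(self):
        sigs = [
            signal("CHB", "1", 100, 900, 0.30, cm=1.0),
            signal("CHB", "1", 2000, 2500, 0.20, cm=0.5),
        ]
        assert len(hs.collapse_to_highest_frequency(sigs)) == 2

    def test_single_signal_passes_through(self):
        s = signal("CHB", "1", 100, 900, 0.30, cm=1.0)
        assert hs.collapse_to_highest_frequency([s]) == [s]

    def test_bin_tie_broken_by_genetic_length_then_start(self):
        a = signal("CHB", "1", 100, 900, 0.40, cm=1.0)
        b = signal("CHB", "1", 200, 950, 0.40, cm=2.0)
        assert hs.collapse_to_highest_frequency([a, b]) == [b]
        c = signal("CHB", "1", 150, 920, 0.40, cm=2.0)
        assert hs.collapse_to_highest_frequency([b, c]) == [c]

    def test_mixed_population_input_rejected(self):
        with pytest.raises(Exception, match="population"):
            hs.collapse_to_highest_frequency(
                [
                    signal("CHB", "1", 1, 10, 0.2, 1.0),
                    signal("CEU", "1", 1, 10, 0.2, 1.0),
                ]
            )


class TestAlleleFrequency:
    def test_monomorphic_column(self):
        panel = make_panel(np.zeros((6, 3), dtype=np.int8))
        assert hs.allele_frequency_on_panel(panel, 0, "A") == 1.0

    def test_count_fraction(self):
        alleles = np.zeros((200, 1), dtype=np.int8)
        alleles[:80, 0] = 1
        panel = make_panel(alleles)
        assert hs.allele_frequency_on_panel(panel, 0, "G") == pytest.approx(0.40)

    def test_unknown_base_rejected(self, toy_panel):
        with pytest.raises(DomainError, match="neither"):
            hs.allele_frequency_on_panel(toy_panel, 0, "T")
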