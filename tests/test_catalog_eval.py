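import numpy as np
import pytest

from haplosweep import catalog_eval as ce
from haplosweep import io_formats, synthetic_data as sd
from haplosweep.types import (
    GwasFixtureRow,
    HaplotypeForm,
    OutgroupAllele,
    SelectionSignal,
)

from conftest import make_panel


def row(rsid="rs1", chrom="1", pos=500_000, risk="G", no_risk="A",
        p=1e-9, trait="T2D", ea=True, eu=False):
    return GwasFixtureRow(
        rsid=rsid,
        chromosome=chrom,
        position_bp=pos,
        no_risk_allele=no_risk,
        risk_allele=risk,
        risk_allele_frequency=0.5,
        nearest_genes=("GENE1",),
        p_value=p,
        odds_ratio=1.2,
        trait=trait,
        reported_east_asian=ea,
        reported_european=eu,
    )


def signal(pop="CHB", chrom="1", start=100_000, end=900_000, sites=((0, 1),),
           score=0.01):
    form = HaplotypeForm(
        chromosome=chrom,
        sites=tuple(sorted(sites)),
        span_start_bp=start,
        span_end_bp=end,
        genetic_length_cm=(end - start) / 1e6,
        snp_count=len(sites),
        carrier_frequency=0.4,
    )
    return SelectionSignal(
        population=pop,
        chromosome=chrom,
        start_bp=start,
        end_bp=end,
        form=form,
        frequency_bin=0.4,
        n_f=100,
        score=score,
        p_cm=0.01,
        p_snp=0.01,
    )


class TestFilterCatalog:
    def test_boundary_p_value_excluded(self):
        rows = [row(p=5e-8)]
        assert ce.filter_catalog(rows) == []

    def test_significant_t2d_row_kept(self):
        rows = [row(p=1e-9)]
        assert len(ce.filter_catalog(rows)) == 1

    def test_empty_input_gives_empty_output(self):
        assert ce.filter_catalog([]) == []

    def test_off_trait_rows_dropped(self):
        rows = [row(trait="height")]
        assert ce.filter_catalog(rows) == []

    def test_duplicate_rsids_collapse_to_most_significant(self):
        rows = [row(p=1e-9), row(p=1e-12)]
        kept = ce.filter_catalog(rows)
        assert len(kept) == 1 and kept[0].p_value == 1e-12


class TestOverlap:
    def test_snp_inside_region_overlaps(self):
        r = row(chrom="2", pos=43_586_327)
        s = signal(pop="CHD", chrom="2", start=43_282_562, end=43_910_360)
        assert ce.overlap_with_signals(r, [s]) == [s]

    def test_printed_chr15_coordinates_do_not_overlap(self):
        r = row(chrom="15", pos=60_183_681)
        s = signal(pop="CHS", chrom="15", start=61_999_328, end=62_941_185)
        assert ce.overlap_with_signals(r, [s]) == []

    @pytest.mark.parametrize("pos", [100_000, 900_000])
    def test_region_boundaries_are_inclusive(self, pos):
        r = row(pos=pos)
        assert len(ce.overlap_with_signals(r, [signal()])) == 1


class TestRiskAlleleOnHaplotype:
    def _panel(self, n=20, m=9):
        # all chromosomes initially allele 0 everywhere
        return make_panel(np.zeros((n, m), dtype=np.int8))

    def test_defining_site_carrying_risk_base(self):
        panel = self._panel()
        panel.alleles[:8, 4] = 1
        s = signal(start=300_000, end=700_000, sites=((2, 0), (4, 1), (6, 0)))
        r = row(pos=500_000, risk="G")  # allele1 == G in make_panel
        assert ce.risk_allele_on_haplotype(r, s, panel) is True

    def test_defining_site_carrying_other_base(self):
        panel = self._panel()
        s = signal(start=300_000, end=700_000, sites=((2, 0), (4, 0), (6, 0)))
        r = row(pos=500_000, risk="G")
        assert ce.risk_allele_on_haplotype(r, s, panel) is False

    def test_non_defining_site_unanimous_carriers(self):
        panel = self._panel()
        panel.alleles[:, 3] = 1  # carriers all share allele1 at SNP 3
        s = signal(start=300_000, end=700_000, sites=((2, 0), (6, 0)))
        r = row(pos=400_000, risk="G")
        assert ce.risk_allele_on_haplotype(r, s, panel) is True

    def test_non_defining_site_split_carriers_indeterminate(self):
        panel = self._panel()
        panel.alleles[:12, 3] = 1  # 60/40 split among the 20 carriers
        s = signal(start=300_000, end=700_000, sites=((2, 0), (6, 0)))
        r = row(pos=400_000, risk="G")
        assert (
            ce.risk_allele_on_haplotype(r, s, panel) == "indeterminate"
        )

    def test_majority_threshold_is_configurable(self):
        panel = self._panel()
        panel.alleles[:12, 3] = 1
        s = signal(start=300_000, end=700_000, sites=((2, 0), (6, 0)))
        r = row(pos=400_000, risk="G")
        assert (
            ce.risk_allele_on_haplotype(r, s, panel, majority_threshold=0.5)
            is True
        )

    def test_snp_outside_span_raises(self):
        panel = self._panel()
        s = signal(start=300_000, end=700_000, sites=((2, 0), (6, 0)))
        with pytest.raises(ce.SpanError):
            ce.risk_allele_on_haplotype(row(pos=800_000), s, panel)


class TestClassifyAncestral:
    def test_risk_matching_outgroup_is_ancestral(self):
        r = row(risk="T", no_risk="C")
        assert ce.classify_ancestral(r, OutgroupAllele(r.rsid, "T")) == "ancestral"

    def test_no_risk_matching_outgroup_means_risk_is_derived(self):
        r = row(risk="C", no_risk="T")
        assert ce.classify_ancestral(r, OutgroupAllele(r.rsid, "T")) == "derived"

    def test_missing_outgroup_base_is_unknown(self):
        r = row()
        assert ce.classify_ancestral(r, OutgroupAllele(r.rsid, None)) == "unknown"
        assert ce.classify_ancestral(r, None) == "unknown"

    def test_mismatching_outgroup_base_is_unknown(self):
        r = row(risk="G", no_risk="A")
        assert ce.classify_ancestral(r, OutgroupAllele(r.rsid, "C")) == "unknown"


class TestEastAsianSpecific:
    EAST = ("CHB", "CHD", "CHS", "JPT")

    def test_reported_in_east_asians_only(self):
        r = row(ea=True, eu=False)
        assoc, _ = ce.east_asian_specific(r, [], self.EAST)
        assert assoc

    def test_reported_in_europeans_is_not_specific(self):
        r = row(ea=False, eu=True)
        assoc, _ = ce.east_asian_specific(r, [], self.EAST)
        assert not assoc

    def test_selection_shared_with_europe_is_not_specific(self):
        sigs = [signal(pop="CHB"), signal(pop="CEU")]
        _, sel = ce.east_asian_specific(row(), sigs, self.EAST)
        assert not sel

    def test_selection_only_in_east_asia_is_specific(self):
        sigs = [signal(pop="CHB"), signal(pop="JPT")]
        _, sel = ce.east_asian_specific(row(), sigs, self.EAST)
        assert sel

    def test_unknown_label_rejected_when_partition_given(self):
        with pytest.raises(Exception, match="unknown population"):
            ce.east_asian_specific(
                row(), [signal(pop="XXX")], self.EAST, known_labels=("CEU",)
            )


class TestEvaluateEndToEnd:
    def test_constructed_supporting_case(self):
        """A derived risk allele on an East-Asian-specific implanted sweep
        is the one configuration that supports the famine-selection
        expectation."""
        cfg = sd.SimConfig(
            seed=11,
            n_populations=2,
            population_labels=("CHB", "CEU"),
            n_snps=120,
            chromosome_length_bp=12_000_000,
            sweep_specs=(
                sd.SweepSpec(
                    start_bp=4_000_000,
                    end_bp=8_000_000,
                    carrier_frequency=0.4,
                    populations=("CHB",),
                    linked_risk_snp=sd.RiskSnpSpec(
                        position_bp=6_000_000,
                        risk_base="G",
                        ancestral_base="A",
                        on_haplotype=True,
                    ),
                ),
            ),
        )
        bundle = sd.simulate(cfg)
        rows, outgroup = sd.emit_catalog(bundle)
        truth = bundle.sweeps[0]
        form = truth.donor_forms["CHB"]
        sig = SelectionSignal(
            population="CHB",
            chromosome="1",
            start_bp=form.span_start_bp,
            end_bp=form.span_end_bp,
            form=form,
            frequency_bin=0.4,
            n_f=100,
            score=0.01,
            p_cm=0.01,
            p_snp=0.01,
        )
        verdicts = ce.evaluate(
            rows,
            [sig],
            {"CHB": [bundle.panels["CHB"]], "CEU": [bundle.panels["CEU"]]},
            outgroup,
            fst_pairs=(("CHB", "CEU"),),
            east_asian_labels=("CHB",),
        )
        (v,) = verdicts
        assert v.overlaps_selection
        assert v.east_asian_specific_selection
        assert v.risk_on_haplotype is True
        assert v.risk_is_derived == "derived"
        assert v.supports_thrifty
        assert len(v.fst_values) == 1

    def test_ancestral_risk_allele_never_supports(self):
        cfg = sd.SimConfig(
            seed=12,
            n_populations=1,
            population_labels=("CHB",),
            n_snps=120,
            chromosome_length_bp=12_000_000,
            sweep_specs=(
                sd.SweepSpec(
                    start_bp=4_000_000,
                    end_bp=8_000_000,
                    carrier_frequency=0.4,
                    populations=("CHB",),
                    linked_risk_snp=sd.RiskSnpSpec(
                        position_bp=6_000_000,
                        risk_base="G",
                        ancestral_base="G",
                        on_haplotype=True,
                    ),
                ),
            ),
        )
        bundle = sd.simulate(cfg)
        rows, outgroup = sd.emit_catalog(bundle)
        truth = bundle.sweeps[0]
        form = truth.donor_forms["CHB"]
        sig = SelectionSignal(
            population="CHB",
            chromosome="1",
            start_bp=form.span_start_bp,
            end_bp=form.span_end_bp,
            form=form,
            frequency_bin=0.4,
            n_f=100,
            score=0.01,
            p_cm=0.01,
            p_snp=0.01,
        )
        (v,) = ce.evaluate(
            rows,
            [sig],
            {"CHB": [bundle.panels["CHB"]]},
            outgroup,
            east_asian_labels=("CHB",),
        )
        assert v.risk_on_haplotype is True
        assert v.risk_is_derived == "ancestral"
        assert not v.supports_thrifty

    def test_verdict_flags_rederivable_from_stored_evidence(self):
        """Every verdict flag is a pure function of the stored evidence."""
        rows, signals, panels, outgroup = sd.fixture_bundle(seed=3)
        verdicts = ce.evaluate(rows, signals, panels, outgroup)
        for v in verdicts:
            assert v.supports_thrifty == (
                v.overlaps_selection
                and v.east_asian_specific_selection
                and v.risk_on_haplotype is True
                and v.risk_is_derived == "derived"
            )
            r = next(x for x in rows if x.rsid == v.rsid)
            assert v.east_asian_specific_association == (
                r.reported_east_asian and not r.reported_european
            )
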