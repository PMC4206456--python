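"""Distinguish shared-origin from convergent sweeps with the HSI.

The same region is swept in two populations either by one donor haplotype
(single ancestral mutation event) or by independent donors (convergent
evolution).  The haplotype similarity index over the shared SNPs of the
two recovered forms separates the scenarios: >0.98 means one event,
<0.9 means convergence.
"""

from haplosweep import haploscan as hs
from haplosweep import similarity as sim
from haplosweep import synthetic_data as sd


def recovered_form(bundle, pop):
    donor = bundle.sweeps[0].donor_forms[pop]
    forms = hs.scan_population(bundle.panels[pop], bins=[0.40])
    signals = hs.score_signals(forms, pop)
    hits = [
        s
        for s in signals
        if s.significant
        and s.start_bp <= donor.span_end_bp
        and s.end_bp >= donor.span_start_bp
    ]
    return max(
        hits, key=lambda s: len(set(s.form.sites) & set(donor.sites))
    ).form


for shared in (True, False):
    config = sd.SimConfig(
        seed=11,
        sweep_specs=(
            sd.SweepSpec(
                start_bp=6_000_000,
                end_bp=10_000_000,
                carrier_frequency=0.40,
                populations=("POP1", "POP2"),
                shared_origin=shared,
            ),
        ),
    )
    bundle = sd.simulate(config)
    a = recovered_form(bundle, "POP1")
    b = recovered_form(bundle, "POP2")
    r = sim.hsi(a, b)
    label = "shared-origin" if shared else "independent donors"
    print(
        f"{label:>18}: HSI = {r.value:.3f} over {r.shared_snp_count} shared "
        f"SNPs -> {r.classification}"
    )

print(
    "\nA shared donor leaves identical selected forms (HSI 1.00); "
    "independent donors agree only at chance level."
)
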