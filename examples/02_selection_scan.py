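"""Scan a panel carrying an implanted hard sweep.

A single donor haplotype spanning 6-10 Mb is copied onto 40% of the
chromosomes of one population; the scan then looks for haplotype forms
that are uncharacteristically long among all forms at the same carrier
frequency.  The score is p_cm * p_snp * n_f (two genome-wide rank
p-values times the candidate count); scores below 0.05 flag selection.
"""

from haplosweep import haploscan as hs
from haplosweep import synthetic_data as sd

config = sd.SimConfig(
    seed=3,
    n_populations=1,
    sweep_specs=(
        sd.SweepSpec(
            start_bp=6_000_000,
            end_bp=10_000_000,
            carrier_frequency=0.40,
            populations=("POP1",),
        ),
    ),
)
bundle = sd.simulate(config)
donor = bundle.sweeps[0].donor_forms["POP1"]
print(
    f"implanted sweep: {donor.snp_count} SNPs, "
    f"{donor.genetic_length_cm:.2f} cM, carrier frequency "
    f"{donor.carrier_frequency:.2f}\n"
)

forms = hs.scan_population(bundle.panels["POP1"], bins=[0.40])
signals = hs.score_signals(forms, "POP1")
significant = [s for s in signals if s.significant]

print(f"candidate forms at bin 0.40: {signals[0].n_f}")
print("significant signals (score < 0.05):")
for s in significant:
    recovered = len(set(s.form.sites) & set(donor.sites))
    print(
        f"  [{s.start_bp:>9,}-{s.end_bp:>10,}] {s.form.snp_count:>3} SNPs "
        f"{s.form.genetic_length_cm:6.2f} cM  score {s.score:.4f}  "
        f"({recovered}/{donor.snp_count} implanted sites recovered)"
    )

print(
    "\nThe implanted haplotype is orders of magnitude longer than any "
    "neutral form at the same frequency, so it ranks first in both length "
    "measures and its score falls far below 0.05."
)
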