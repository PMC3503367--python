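"""Collect the 29-attribute vector for one candidate inside its context.

Builds a miRNA-like hairpin (mature 21-mer, 12-nt loop, perfect star),
locates the star partner, folds the operative precursor region and prints
the attributes that feed the classifier.
"""

import numpy as np

from plantmir import CandidateContext, collect_attributes, reverse_complement

rng = np.random.default_rng(0)
bases = np.array(list("ACGT"))

mirna = "".join(rng.choice(bases, 21))
loop = "".join(rng.choice(bases, 12))
flank5 = "".join(rng.choice(bases, 60))
flank3 = "".join(rng.choice(bases, 60))
context = flank5 + mirna + loop + reverse_complement(mirna) + flank3

ctx = CandidateContext(
    candidate=mirna,
    context=context,
    candidate_offset=len(flank5),
    chrom_length=len(context),
    chrom_position=len(flank5) + 1,
)
vec = collect_attributes(ctx, side="downstream_star", vector_id="example")

print(f"candidate  {mirna}")
print(f"OPR length {len(vec.opr)} nt, fold {vec.opr.dot_bracket}")
for name in ("DuplexEnergy", "DuplexEnergyNorm", "MaxMismatch", "minMatchPercent",
             "DeltaG", "DeltaGnorm", "ShannonEntropyNorm", "G+C"):
    print(f"{name:>20}: {vec.values[name]:.4f}")
print()
print("A perfect planted duplex shows MaxMismatch 0 and minMatchPercent 100;")
print("DeltaG (the folded stem-loop energy) is at least as negative as the")
print("duplex energy because the hairpin contains the duplex.")
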