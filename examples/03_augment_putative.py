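"""Find putative (assumed-inactive) off-target loci by genome scan.

Plants near-copies of an experimental target in a small synthetic
genome and scans both strands for 23 bp windows within six mismatches
(fewer than seven) of the seed.
"""

import numpy as np

from nucleoff import augment_putative
from nucleoff.records import OffTargetRecord, reverse_complement

rng = np.random.default_rng(2)
genome = list(rng.choice(list("ACGT"), size=8000))
target = "".join(rng.choice(list("ACGT"), size=23))

for pos, n_mut in ((1000, 0), (2500, 4), (4000, 6), (5500, 7)):
    copy = list(target)
    for p in rng.choice(23, size=n_mut, replace=False):
        copy[p] = rng.choice([b for b in "ACGT" if b != copy[p]])
    genome[pos : pos + 23] = copy
genome[6500 : 6500 + 23] = list(reverse_complement(target))
genome = "".join(genome)

seed = OffTargetRecord(
    record_id="seed", grna_seq=target, target_seq=target,
    context_seq="A" * 73 + target + "A" * 73, chrom="demo", pos=999_999,
    strand="+", study_id="s", cell_line="HeLa", cleavage_rate=0.3,
    cleavage_activity=1.2, is_putative=False,
)
hits = augment_putative(genome, [seed])
print(f"{len(hits)} putative records (each CA=-4, is_putative=True):")
for h in sorted(hits, key=lambda h: h.pos):
    mm = sum(a != b for a, b in zip(h.target_seq, target))
    print(f"  pos {h.pos:5d} strand {h.strand}  mismatches={mm}")
print("\nThe 7-mismatch plant at 4000+1500 is correctly absent ('fewer than seven').")
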