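"""Call predicted G-quadruplexes (pG4s) on a small sequence.

Builds a toy contig containing a telomeric G-repeat, scores it with the
run-length G4Hunter rule and prints the called intervals.  The score is
the mean per-base score over the region: G-runs of length n contribute
+min(n, 4) per base, C-runs the negative; a region on the - strand is a
C-rich stretch whose complement would fold into a G4.
"""

from g4access import G4HunterParams, GenomeSequence, base_scores, call_pg4

telomeric = "GGGTTAGGGTTAGGGTTAGGGTTA"
genome = GenomeSequence()
genome.add("toy", "ACGATTAGCAT" * 5 + telomeric + "TACGATTACGA" * 5)

print("base scores of 'AGGGTC':", base_scores("AGGGTC").tolist())

for region in call_pg4(genome, G4HunterParams(window=24, threshold=1.2)):
    print(f"pG4 at {region.contig}:{region.start}-{region.end} "
          f"({region.strand}) score={region.score:.2f}")
# One + strand call over the planted repeat (plus a few flanking bases
# swept in by the window union): twelve G bases scoring +3 each keep the
# region mean above the 1.2 threshold.
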