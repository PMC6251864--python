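"""Generate a synthetic transcriptome with tissue-specific m5C sites.

Builds a small set of background transcripts, implants each tissue's
C-anchored motif, and prints how many candidate C's and recorded positives
each tissue carries — the class imbalance every later step has to cope with.
"""

from m5cpred import SyntheticSpec, simulate

spec = SyntheticSpec(n_transcripts=20, length_range=(800, 1200), seed=42)
transcripts, site_tables = simulate(spec)

total_c = sum(t.sequence.count("C") for t in transcripts)
print(f"{len(transcripts)} transcripts, {total_c} candidate C sites")
for tissue, records in site_tables.items():
    motif = spec.motif_per_tissue[tissue]
    print(f"  {tissue:13s} motif {motif}: {len(records):3d} positives "
          f"(~1 per {total_c // len(records)} candidates)")

# Each positive is one cytosine to classify; everything else C-shaped is a
# potential false positive, which is why ROC/AUC (not accuracy) is the
# metric of record.
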