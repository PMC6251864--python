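"""Extract a candidate-C window and encode it both ways.

Shows the 21-nt window around a cytosine (w=10), its one-hot encoding
(4 identity bits per position) and the physicochemical+frequency
alternative; both yield 84 features.
"""

from m5cpred import SyntheticSpec, simulate, extract_window
from m5cpred.encode import feng_encode, one_hot_encode

spec = SyntheticSpec(n_transcripts=5, length_range=(500, 600), seed=7)
transcripts, tables = simulate(spec)
by_id = {t.id: t for t in transcripts}

tissue = spec.tissues[0]
site = tables[tissue][0]
window = extract_window(by_id[site.transcript_id], site.position, w=10)
print(f"site {site.transcript_id}:{site.position} ({tissue})")
print(f"window  5'-{window.bases}-3'  (centre base: {window.bases[10]})")

one_hot = one_hot_encode(window)
feng = feng_encode(window)
print(f"one-hot : {len(one_hot.values)} features; "
      f"first position {one_hot.values[:4]}")
print(f"feng    : {len(feng.values)} features; "
      f"first position {feng.values[:4]}")
# In the feng scheme the 4th component is the running frequency of that
# base within the window so far; the first three bits encode ring number,
# chemical functionality and hydrogen-bond count.
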