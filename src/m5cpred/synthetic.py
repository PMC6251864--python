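"""Synthetic transcriptomes with implanted, tissue-specific m5C motifs.

The generator stands in for experimentally mapped m5C site sets so that the
whole pipeline — window extraction, encoding, ratio-controlled dataset
construction, training, calibration, and the intra-/inter-tissue benchmark
— can be exercised end to end without any external download.

What it emulates
----------------
* Background transcripts as i.i.d. draws from a base-composition
  multinomial (default uniform), lengths uniform in a range.
* Per tissue, a distinct sequence motif anchored on a C: positives are
  implanted occurrences of that motif (the anchor C is recorded as a
  positive site). Real modification context preference is statistical, not
  an exact consensus, so each non-anchor motif position matches its
  consensus base with probability ``motif_fidelity`` (default 0.85) and is
  otherwise substituted — a position-weight-matrix signal that keeps
  held-out AUC high without degenerate perfect separation.
* Realistic candidate-class imbalance: with the defaults each transcript
  carries a few positives among hundreds of unmodified C's (roughly one
  positive per 150-plus candidates), so 1:k training subsampling and the
  1:all test convention are both meaningful.
* Optional label noise: each implanted positive is recorded as a negative
  with probability ``label_noise``, and a matching expected number of
  background C's are recorded as spurious positives.

Implantation overwrites the background sequence at the sampled locus
(rejection-sampling a motif-free background would distort the positive
rate); loci are sampled without overlap so one tissue's motif never
destroys another's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import SyntheticSpecError
from .seqio import SiteRecord, Transcript, write_fasta, write_site_table

_BASES = "ACGT"

#: Default tissue motifs: 9-mers, anchor C at the centre (offset 4), chosen
#: pairwise-distinct at 6+ of the 8 flanking positions so tissue-specific
#: predictors have genuinely different signals to learn.
DEFAULT_MOTIFS: dict[str, str] = {
    "mouse_Heart": "AAGGCGGAA",
    "mouse_Brain": "TTACCATTT",
    "human_Hela": "CGTTCTTGC",
}


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``positive_rate`` is the expected number of implanted sites per
    transcript per tissue (realised counts are Poisson). ``label_noise``
    is the probability that a recorded label is flipped; 0 ≤ noise < 0.5.
    """

    n_transcripts: int = 100
    length_range: tuple[int, int] = (1500, 2500)
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    tissues: tuple[str, ...] = tuple(DEFAULT_MOTIFS)
    motif_per_tissue: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS))
    positive_rate: float = 3.0
    motif_fidelity: float = 0.85
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise SyntheticSpecError("n_transcripts must be >= 1")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise SyntheticSpecError(f"bad length_range {self.length_range}")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any():
            raise SyntheticSpecError("base_composition needs 4 non-negative "
                                     "probabilities")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise SyntheticSpecError("base_composition must sum to 1")
        if comp[_BASES.index("C")] == 0.0:
            raise SyntheticSpecError(
                "composition gives C probability 0: no candidate sites can "
                "exist"
            )
        if not 0.0 <= self.label_noise < 0.5:
            raise SyntheticSpecError("label_noise must be in [0, 0.5)")
        if not 0.25 <= self.motif_fidelity <= 1.0:
            raise SyntheticSpecError(
                "motif_fidelity below background (0.25) carries no signal"
            )
        for tissue in self.tissues:
            motif = self.motif_per_tissue.get(tissue)
            if motif is None:
                raise SyntheticSpecError(f"tissue {tissue!r} has no motif")
            if set(motif) - set("ACGTN"):
                raise SyntheticSpecError(f"motif {motif!r} has bad characters")
            if motif[self.anchor_offset(tissue)] != "C":
                raise SyntheticSpecError(
                    f"motif {motif!r} lacks a C at its anchor position"
                )

    def anchor_offset(self, tissue: str) -> int:
        """0-based offset of the anchor C within the tissue's motif (centre)."""
        return len(self.motif_per_tissue[tissue]) // 2

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["length_range"] = list(self.length_range)
        payload["base_composition"] = list(self.base_composition)
        payload["tissues"] = list(self.tissues)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        payload = json.loads(Path(path).read_text())
        payload["length_range"] = tuple(payload["length_range"])
        payload["base_composition"] = tuple(payload["base_composition"])
        payload["tissues"] = tuple(payload["tissues"])
        return cls(**payload)


def generate_transcripts(spec: SyntheticSpec,
                         rng: np.random.Generator | None = None,
                         ) -> list[Transcript]:
    """Background transcripts: i.i.d. bases from the spec composition."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    lo, hi = spec.length_range
    transcripts = []
    width = len(str(spec.n_transcripts))
    for i in range(spec.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(
            np.array(list(_BASES))[
                rng.choice(4, size=length, p=spec.base_composition)
            ]
        )
        transcripts.append(
            Transcript(id=f"synt{i + 1:0{width}d}", sequence=seq,
                       gene_id=f"syng{i + 1:0{width}d}", biotype="mRNA")
        )
    return transcripts


def _sample_loci(rng: np.random.Generator, seq_len: int, motif_len: int,
                 count: int, occupied: set[int]) -> list[int]:
    """Non-overlapping 0-based start positions; rejection with an attempt
    cap so pathological densities terminate."""
    chosen: list[int] = []
    attempts = 0
    max_attempts = 200 * max(count, 1)
    while len(chosen) < count and attempts < max_attempts:
        attempts += 1
        start = int(rng.integers(0, seq_len - motif_len + 1))
        span = range(start, start + motif_len)
        if any(p in occupied for p in span):
            continue
        chosen.append(start)
        occupied.update(span)
    return chosen


def implant_sites(transcripts: Sequence[Transcript], spec: SyntheticSpec,
                  rng: np.random.Generator | None = None,
                  ) -> tuple[list[Transcript], dict[str, list[SiteRecord]]]:
    """Write each tissue's motif into the transcripts and record site tables.

    Returns the modified transcripts and one site table per tissue. The
    anchor C of every implant is recorded as a positive (subject to label
    noise); all other C's remain implicit negatives for the dataset
    builder to enumerate.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    shortest = min(len(t.sequence) for t in transcripts)
    longest_motif = max(len(m) for m in spec.motif_per_tissue.values())
    if longest_motif > shortest:
        raise SyntheticSpecError(
            f"motif length {longest_motif} exceeds shortest transcript "
            f"({shortest} nt)"
        )

    sequences = {t.id: list(t.sequence) for t in transcripts}
    occupied: dict[str, set[int]] = {t.id: set() for t in transcripts}
    tables: dict[str, list[SiteRecord]] = {}
    implanted: dict[str, list[tuple[str, int]]] = {}

    for tissue in spec.tissues:
        motif = spec.motif_per_tissue[tissue]
        anchor = spec.anchor_offset(tissue)
        implanted[tissue] = []
        for t in transcripts:
            n_sites = int(rng.poisson(spec.positive_rate))
            if n_sites == 0:
                continue
            starts = _sample_loci(rng, len(t.sequence), len(motif), n_sites,
                                  occupied[t.id])
            for start in starts:
                for offset, base in enumerate(motif):
                    if offset == anchor:
                        base = "C"  # the candidate site itself is never mutated
                    elif base == "N":
                        base = _BASES[rng.choice(4, p=spec.base_composition)]
                    elif rng.random() >= spec.motif_fidelity:
                        others = [b for b in _BASES if b != base]
                        base = others[int(rng.integers(3))]
                    sequences[t.id][start + offset] = base
                implanted[tissue].append((t.id, start + anchor + 1))

    mutated = [
        Transcript(id=t.id, sequence="".join(sequences[t.id]),
                   gene_id=t.gene_id, biotype=t.biotype)
        for t in transcripts
    ]
    by_id = {t.id: t for t in mutated}

    for tissue in spec.tissues:
        records: list[SiteRecord] = []
        true_keys = set(implanted[tissue])
        n_flipped_pos = 0
        for tid, pos in implanted[tissue]:
            label = "positive"
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                label = "negative"
                n_flipped_pos += 1
            records.append(SiteRecord(transcript_id=tid, position=pos,
                                      label=label, tissue=tissue))
        if spec.label_noise > 0 and implanted[tissue]:
            # spurious positives: background C's promoted at the noise rate
            n_false = int(rng.binomial(len(implanted[tissue]),
                                       spec.label_noise))
            pool = sorted(
                (t.id, i + 1)
                for t in mutated
                for i, base in enumerate(t.sequence)
                if base == "C" and (t.id, i + 1) not in true_keys
            )
            if n_false and pool:
                picks = rng.choice(len(pool), size=min(n_false, len(pool)),
                                   replace=False)
                for idx in sorted(picks):
                    tid, pos = pool[idx]
                    records.append(SiteRecord(transcript_id=tid, position=pos,
                                              label="positive", tissue=tissue))
        # guard: every recorded site must sit on a C of the final sequence
        records = [r for r in records
                   if by_id[r.transcript_id].sequence[r.position - 1] == "C"]
        tables[tissue] = sorted(records, key=lambda r: r.key)
    return mutated, tables


def simulate(spec: SyntheticSpec,
             ) -> tuple[list[Transcript], dict[str, list[SiteRecord]]]:
    """Generate background transcripts and implant every tissue's sites,
    all from the single seed in the spec."""
    rng = np.random.default_rng(spec.seed)
    background = generate_transcripts(spec, rng)
    return implant_sites(background, spec, rng)


def write_simulation(transcripts: Sequence[Transcript],
                     tables: Mapping[str, Sequence[SiteRecord]],
                     spec: SyntheticSpec, out_dir: str | Path) -> None:
    """Persist a simulation as the standard FASTA + single TSV (tissue
    column distinguishes tables) + the spec as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(transcripts, out / "transcripts.fasta")
    all_records = [r for tissue in sorted(tables) for r in tables[tissue]]
    write_site_table(all_records, out / "sites.tsv")
    spec.to_json(out / "spec.json")
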