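"""Desk-scale synthetic proteome with planted, learnable sequence->function
structure.

Each GO-like class carries one short motif (a 4-8 residue k-mer); a protein
annotated with a class contains that class's motif verbatim at a random,
non-overlapping position inside an i.i.d. background sequence.  Class
membership is therefore statistically detectable from sequence content — the
property the real training corpus has and the end-to-end tests need — while
everything else about real proteomes (domain grammar, homology families,
secondary structure) is deliberately absent.  A ground-truth manifest records
every planted label and motif position, serving as the oracle for tests.

Label permutation (the negative control) shuffles the accession column of
the annotation table, preserving per-class counts while destroying the
motif-label association.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seqio import (AMINO_ACIDS, AnnotationTable, ProteinRecord,
                    write_annotations, write_fasta)

__all__ = [
    "SyntheticDesign",
    "SyntheticManifest",
    "generate_corpus",
    "permute_annotation_rows",
    "permute_labels",
    "UNIPROT_FREQUENCIES",
]

# Swiss-Prot release-wide amino-acid composition (fractions, order ACDEFGHIKLMNPQRSTVWY)
UNIPROT_FREQUENCIES = np.array([
    0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0665, 0.0535, 0.0686,
    0.0110, 0.0292,
])
UNIPROT_FREQUENCIES = UNIPROT_FREQUENCIES / UNIPROT_FREQUENCIES.sum()


@dataclass
class SyntheticDesign:
    """Parameters of the planted-motif corpus.

    Defaults are the desk-scale study conditions: 8 classes, 320 proteins,
    sequence lengths 80-160, 1-3 labels per protein, motif length 4-8,
    uniform residue background (so class signal comes from motifs, not
    composition).  ``class_counts`` switches to an exact per-class design
    (each class annotated on exactly that many proteins), used to exercise
    the eligibility / top-k selection rules.
    """

    n_classes: int = 8
    n_proteins: int = 320
    min_len: int = 80
    max_len: int = 160
    labels_min: int = 1
    labels_max: int = 3
    motif_len_min: int = 4
    motif_len_max: int = 8
    background: str = "uniform"  # "uniform" | "uniprot-like"
    class_weight_decay: float = 0.7  # Zipf exponent for long-tailed class frequencies
    class_counts: list | None = None
    seed: int = 0

    def __post_init__(self):
        if self.class_counts is not None:
            self.class_counts = [int(c) for c in self.class_counts]
            self.n_classes = len(self.class_counts)
        if self.n_classes < 1 or self.n_proteins < 1:
            raise ValueError("n_classes and n_proteins must be >= 1")
        if not 1 <= self.motif_len_min <= self.motif_len_max:
            raise ValueError("invalid motif length bounds")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("invalid sequence length bounds")
        if self.labels_min < 0 or self.labels_max < self.labels_min:
            raise ValueError("invalid labels-per-protein bounds")
        if self.labels_max > self.n_classes:
            raise ValueError("labels_max cannot exceed n_classes")
        if self.background not in ("uniform", "uniprot-like"):
            raise ValueError("background must be 'uniform' or 'uniprot-like'")

    def residue_probs(self) -> np.ndarray:
        if self.background == "uniform":
            return np.full(20, 1.0 / 20.0)
        return UNIPROT_FREQUENCIES.copy()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticDesign":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class SyntheticManifest:
    """Ground truth of a generated corpus (the test oracle)."""

    design: dict
    motifs: dict                 # class id -> motif string
    proteins: list               # per protein: accession, classes, motif positions, length
    class_counts: dict           # class id -> number of distinct annotated proteins

    def label_pairs(self) -> set:
        return {(p["accession"], go) for p in self.proteins for go in p["classes"]}

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def read_json(cls, path) -> "SyntheticManifest":
        return cls(**json.loads(Path(path).read_text()))


def _draw_motifs(rng: np.random.Generator, design: SyntheticDesign) -> list:
    """Distinct motifs, none a substring of another."""
    motifs: list = []
    tries = 0
    while len(motifs) < design.n_classes:
        tries += 1
        if tries > 1000 * design.n_classes:
            raise RuntimeError("could not draw substring-free motif set; "
                               "loosen motif length bounds or reduce n_classes")
        k = int(rng.integers(design.motif_len_min, design.motif_len_max + 1))
        m = "".join(rng.choice(list(AMINO_ACIDS), size=k))
        if any(m in other or other in m for other in motifs):
            continue
        motifs.append(m)
    return motifs


def _assign_labels(rng: np.random.Generator, design: SyntheticDesign) -> list:
    """Class sets per protein: exact designed counts, or random long-tailed."""
    n, C = design.n_proteins, design.n_classes
    labels: list = [set() for _ in range(n)]
    if design.class_counts is not None:
        order = np.argsort(design.class_counts)[::-1]
        for k in order:
            need = design.class_counts[k]
            open_slots = [i for i in range(n) if len(labels[i]) < design.labels_max]
            if need > len(open_slots):
                raise ValueError(
                    f"class counts infeasible: class {k} needs {need} proteins, "
                    f"only {len(open_slots)} have open label slots"
                )
            for i in rng.choice(open_slots, size=need, replace=False):
                labels[i].add(int(k))
        return [sorted(s) for s in labels]
    weights = (np.arange(C) + 1.0) ** (-design.class_weight_decay)
    weights /= weights.sum()
    for i in range(n):
        m = int(rng.integers(design.labels_min, design.labels_max + 1))
        if m > 0:
            chosen = rng.choice(C, size=m, replace=False, p=weights)
            labels[i] = set(int(c) for c in chosen)
    return [sorted(s) for s in labels]


def _place_motifs(rng, length, motif_list):
    """Non-overlapping placement: distribute free residues into random gaps."""
    total = sum(len(m) for m in motif_list)
    free = length - total
    order = rng.permutation(len(motif_list))
    cuts = np.sort(rng.integers(0, free + 1, size=len(motif_list)))
    positions = {}
    cursor = 0
    prev_cut = 0
    for rank, mi in enumerate(order):
        gap = int(cuts[rank] - prev_cut)
        prev_cut = cuts[rank]
        cursor += gap
        positions[int(mi)] = cursor
        cursor += len(motif_list[mi])
    return positions


def generate_corpus(design: SyntheticDesign, out_dir=None):
    """Generate (records, annotation table, manifest); deterministic per seed.

    Background residues are i.i.d. from the design's residue frequencies;
    each assigned class's motif is substituted in at a non-overlapping random
    position.  Sequences too short to hold all their motifs are lengthened to
    fit (flagged in the manifest).  When ``out_dir`` is given, writes
    corpus.fasta, annotations.tsv and manifest.json.
    """
    rng = np.random.default_rng(design.seed)
    motifs = _draw_motifs(rng, design)
    labels = _assign_labels(rng, design)
    probs = design.residue_probs()
    alphabet = np.array(list(AMINO_ACIDS))
    records, proteins = [], []
    width = len(str(design.n_proteins))
    for i in range(design.n_proteins):
        acc = f"SYN{i:0{width}d}"
        length = int(rng.integers(design.min_len, design.max_len + 1))
        motif_list = [motifs[k] for k in labels[i]]
        total_motif = sum(len(m) for m in motif_list)
        lengthened = False
        if total_motif > length:
            length = total_motif
            lengthened = True
        seq = rng.choice(alphabet, size=length, p=probs)
        placed = {}
        if motif_list:
            pos = _place_motifs(rng, length, motif_list)
            for mi, start in pos.items():
                m = motif_list[mi]
                seq[start:start + len(m)] = list(m)
                placed[f"GO:{labels[i][mi]:07d}"] = int(start)
        sequence = "".join(seq)
        records.append(ProteinRecord(accession=acc, sequence=sequence))
        proteins.append({
            "accession": acc,
            "classes": [f"GO:{k:07d}" for k in labels[i]],
            "motif_positions": placed,
            "length": length,
            "lengthened": lengthened,
        })
    pairs = {(p["accession"], go) for p in proteins for go in p["classes"]}
    table = AnnotationTable(pairs=pairs)
    manifest = SyntheticManifest(
        design=design.to_dict(),
        motifs={f"GO:{k:07d}": motifs[k] for k in range(design.n_classes)},
        proteins=proteins,
        class_counts={go: c for go, c in sorted(table.class_counts.items())},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "corpus.fasta")
        write_annotations(pairs, out_dir / "annotations.tsv")
        manifest.write_json(out_dir / "manifest.json")
    return records, table, manifest


def permute_annotation_rows(rows, seed: int):
    """Shuffle the accession column across rows; class counts are unchanged."""
    rows = list(rows)
    rng = np.random.default_rng(seed)
    accs = [acc for acc, _ in rows]
    perm = rng.permutation(len(rows))
    return [(accs[perm[i]], go) for i, (_, go) in enumerate(rows)]


def permute_labels(in_path, out_path, seed: int) -> None:
    """File-level negative control: permute the accession column of a
    two-column annotation TSV."""
    rows = []
    with open(in_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                acc, go = line.split("\t")
                rows.append((acc, go))
    out = permute_annotation_rows(rows, seed)
    with open(out_path, "w") as fh:
        for acc, go in out:
            fh.write(f"{acc}\t{go}\n")
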