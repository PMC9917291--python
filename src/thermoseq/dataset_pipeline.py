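"""Dataset-construction filter chain.

Order of operations mirrors how the benchmark corpus is built from an
OGT-annotated sequence collection:

1. class assignment from optimal growth temperature (thermophilic at
   >= 60 degrees C, mesophilic at <= 37 degrees C, the band in between
   excluded);
2. fragment drop and length filter (strictly more than 1500 residues
   excluded);
3. redundancy removal at 40% pairwise identity (built-in greedy global
   alignment clustering, or delegation to the external CD-HIT program);
4. class balancing by seeded undersampling of the majority class, or a
   deliberately unbalanced 30:1800 test draw.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import LABEL_MESOPHILIC, LABEL_THERMOPHILIC, ProteinRecord

CLASS_EXCLUDED = "excluded"
THERMOPHILIC_MIN_OGT = 60.0
MESOPHILIC_MAX_OGT = 37.0
MAX_RESIDUES = 1500
IDENTITY_CUTOFF = 0.40


def assign_class(ogt: float) -> str:
    """Thermophilic at OGT >= 60 C, mesophilic at <= 37 C, else excluded."""
    if ogt is None or not np.isfinite(ogt):
        raise ValueError("missing or non-finite optimal growth temperature")
    if ogt >= THERMOPHILIC_MIN_OGT:
        return LABEL_THERMOPHILIC
    if ogt <= MESOPHILIC_MAX_OGT:
        return LABEL_MESOPHILIC
    return CLASS_EXCLUDED


def label_by_ogt(records: Iterable[ProteinRecord]) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Assign labels from OGT; records in the excluded band are returned second."""
    kept, excluded = [], []
    for r in records:
        cls = assign_class(r.ogt)
        if cls == CLASS_EXCLUDED:
            excluded.append(r)
        else:
            r.label = cls
            kept.append(r)
    return kept, excluded


def drop_fragments(records: Iterable[ProteinRecord]) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Drop records whose description carries the token 'fragment'."""
    kept, dropped = [], []
    for r in records:
        (dropped if "fragment" in r.description.lower() else kept).append(r)
    return kept, dropped


def length_filter(
    records: Iterable[ProteinRecord], max_len: int = MAX_RESIDUES
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Keep records of at most ``max_len`` residues (strict rejection above)."""
    accepted, rejected = [], []
    for r in records:
        (accepted if len(r) <= max_len else rejected).append(r)
    return accepted, rejected


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity = matches / alignment columns under global affine alignment."""
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def identity_cluster(
    records: Sequence[ProteinRecord],
    cutoff: float = IDENTITY_CUTOFF,
    use_cdhit: bool = False,
) -> list[ProteinRecord]:
    """Greedy longest-first identity clustering; returns representatives.

    A record joins the first existing cluster whose representative it
    matches at >= ``cutoff`` identity, otherwise it founds a new cluster.
    The built-in path is quadratic and meant for fixtures and tests; for
    production-scale corpora set ``use_cdhit=True`` to delegate to the
    CD-HIT program.
    """
    if use_cdhit:
        return _cdhit_cluster(records, cutoff)
    aligner = _make_aligner()
    reps: list[ProteinRecord] = []
    for rec in sorted(records, key=lambda r: (-len(r), r.id)):
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence, aligner) >= cutoff:
                break
        else:
            reps.append(rec)
    order = {r.id: i for i, r in enumerate(records)}
    return sorted(reps, key=lambda r: order[r.id])


def _cdhit_cluster(records: Sequence[ProteinRecord], cutoff: float) -> list[ProteinRecord]:
    exe = shutil.which("cd-hit")
    if exe is None:
        raise RuntimeError(
            "cd-hit executable not found on PATH; use the built-in "
            "clustering path (use_cdhit=False) or install CD-HIT"
        )
    from .io import write_fasta  # local import to avoid cycle at module load

    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fout = Path(tmp) / "out"
        write_fasta(records, fin)
        word = 2 if cutoff < 0.5 else 3
        subprocess.run(
            [exe, "-i", str(fin), "-o", str(fout), "-c", str(cutoff),
             "-n", str(word)],
            check=True, capture_output=True,
        )
        accepted = _read_cdhit_output(fout)
    by_id = {r.id: r for r in records}
    return [by_id[i] for i in accepted if i in by_id]


def _read_cdhit_output(fout: Path) -> list[str]:
    ids: list[str] = []
    with open(fout) as fh:
        for line in fh:
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
    return ids


def balance_undersample(
    pos: Sequence[ProteinRecord],
    neg: Sequence[ProteinRecord],
    seed: int,
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Equalize class sizes by seeded uniform sampling without replacement."""
    if not pos or not neg:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    pos, neg = list(pos), list(neg)
    target = min(len(pos), len(neg))

    def take(group: list[ProteinRecord]) -> list[ProteinRecord]:
        if len(group) == target:
            return group
        idx = sorted(rng.choice(len(group), size=target, replace=False))
        return [group[i] for i in idx]

    return take(pos), take(neg)


def make_unbalanced_split(
    pos_pool: Sequence[ProteinRecord],
    neg_pool: Sequence[ProteinRecord],
    n_pos: int = 30,
    n_neg: int = 1800,
    seed: int = 0,
    exclude_ids: Iterable[str] = (),
) -> list[ProteinRecord]:
    """Seeded draw of an unbalanced test set (default 30 : 1800, i.e. 1:60).

    Records whose id is in ``exclude_ids`` (e.g. the training set) are never
    drawn, keeping the split disjoint from training.
    """
    excluded = set(exclude_ids)
    pos_pool = [r for r in pos_pool if r.id not in excluded]
    neg_pool = [r for r in neg_pool if r.id not in excluded]
    if len(pos_pool) < n_pos or len(neg_pool) < n_neg:
        raise ValueError(
            f"insufficient pool: need {n_pos}+/{n_neg}- but have "
            f"{len(pos_pool)}+/{len(neg_pool)}-"
        )
    rng = np.random.default_rng(seed)
    pos_idx = sorted(rng.choice(len(pos_pool), size=n_pos, replace=False))
    neg_idx = sorted(rng.choice(len(neg_pool), size=n_neg, replace=False))
    return [pos_pool[i] for i in pos_idx] + [neg_pool[i] for i in neg_idx]


def build_dataset(
    records: Sequence[ProteinRecord],
    seed: int = 0,
    cutoff: float = IDENTITY_CUTOFF,
    cluster: bool = True,
    use_cdhit: bool = False,
) -> dict:
    """Run the full filter chain and return the intermediate stages.

    Returns a dict with keys ``labelled``, ``ogt_excluded``, ``fragments``,
    ``too_long``, ``representatives``, ``balanced_pos``, ``balanced_neg``.
    """
    labelled, ogt_excluded = label_by_ogt(records)
    labelled, fragments = drop_fragments(labelled)
    labelled, too_long = length_filter(labelled)
    reps = identity_cluster(labelled, cutoff, use_cdhit) if cluster else list(labelled)
    pos = [r for r in reps if r.label == LABEL_THERMOPHILIC]
    neg = [r for r in reps if r.label == LABEL_MESOPHILIC]
    bal_pos, bal_neg = balance_undersample(pos, neg, seed) if pos and neg else (pos, neg)
    return {
        "labelled": labelled,
        "ogt_excluded": ogt_excluded,
        "fragments": fragments,
        "too_long": too_long,
        "representatives": reps,
        "balanced_pos": bal_pos,
        "balanced_neg": bal_neg,
    }
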