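"""Billboard-model synthetic dataset with base-resolution ground truth.

Each sequence is 200 nt drawn from an equiprobable background into which 3-5
motifs are embedded at non-overlapping random positions.  Positive-class
sequences draw motifs (with replacement) from the core pool; negative-class
sequences draw from the combined core+background pool, so negatives can
contain core motifs but rarely a positive regulatory combination.  The
per-position sampling probabilities — motif PFM columns inside placements,
uniform 0.25 elsewhere — are retained as the ground-truth matrix, giving
pixel-level truth for scoring attribution maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .containers import DNA_ALPHABET, GroundTruthMatrix
from .motifs import MotifLibrary, PFM

_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

DEFAULT_LENGTH = 200
DEFAULT_FRACTIONS = (0.7, 0.1, 0.2)
_PLACEMENT_RETRIES = 1000


@dataclass
class AnnotatedSequence:
    """A one-hot sequence with its label, ground truth and motif placements."""

    onehot: np.ndarray
    label: int
    ground_truth: GroundTruthMatrix
    motif_placements: list[tuple[str, int, int]] = field(default_factory=list)
    sequence_id: str = ""

    def __post_init__(self) -> None:
        oh = np.asarray(self.onehot, dtype=np.float32)
        if oh.ndim != 2 or oh.shape[1] != 4:
            raise ValueError("onehot must be (L, 4)")
        if not (np.all((oh == 0) | (oh == 1)) and np.all(oh.sum(axis=1) == 1)):
            raise ValueError("onehot rows must contain exactly one 1")
        self.onehot = oh
        self.label = int(self.label)
        ends = sorted((s, e) for _, s, e in self.motif_placements)
        for (s1, e1), (s2, e2) in zip(ends, ends[1:]):
            if s2 < e1:
                raise ValueError("motif placements overlap")

    @property
    def string(self) -> str:
        return "".join(DNA_ALPHABET[i] for i in self.onehot.argmax(axis=1))


@dataclass
class DatasetSplits:
    """Train/validation/test partitions of annotated sequences."""

    train: list[AnnotatedSequence]
    valid: list[AnnotatedSequence]
    test: list[AnnotatedSequence]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0

    def split(self, name: str) -> list[AnnotatedSequence]:
        return getattr(self, name)

    def arrays(self, name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stack a split into (X, y, M) arrays: one-hot, labels, ground truth."""
        seqs = self.split(name)
        X = np.stack([s.onehot for s in seqs]).astype(np.float32)
        y = np.array([s.label for s in seqs], dtype=np.int64)
        M = np.stack([s.ground_truth.probs for s in seqs])
        return X, y, M


def onehot_from_string(seq: str) -> np.ndarray:
    oh = np.zeros((len(seq), 4), dtype=np.float32)
    for i, ch in enumerate(seq.upper()):
        oh[i, _BASE_INDEX[ch]] = 1.0
    return oh


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _place_motifs(
    motifs: list[PFM], length: int, rng: np.random.Generator
) -> list[tuple[PFM, int]]:
    """Uniform random non-overlapping starts via rejection sampling."""
    placed: list[tuple[PFM, int]] = []
    occupied: list[tuple[int, int]] = []
    for idx, motif in enumerate(motifs):
        w = motif.width
        if w > length:
            raise ValueError(f"motif {motif.name!r} (width {w}) exceeds sequence length {length}")
        for _ in range(_PLACEMENT_RETRIES):
            start = int(rng.integers(0, length - w + 1))
            if all(start + w <= s or start >= e for s, e in occupied):
                occupied.append((start, start + w))
                placed.append((motif, start))
                break
        else:
            raise RuntimeError(
                f"could not place motif draw {idx} ({motif.name!r}, width {w}) without "
                f"overlap after {_PLACEMENT_RETRIES} retries"
            )
    return placed


def sample_sequence(
    label: int,
    library: MotifLibrary | None = None,
    length: int = DEFAULT_LENGTH,
    rng_seed=None,
    sequence_id: str = "",
) -> AnnotatedSequence:
    """Draw one annotated sequence of the requested class.

    The motif count k is uniform on {3, 4, 5}; motifs are drawn with
    replacement from the core pool (label 1) or core+background pool
    (label 0) and placed at non-overlapping uniform starts.  The ground-truth
    matrix holds each placement's PFM columns and 0.25 elsewhere, and every
    nucleotide is sampled from its ground-truth row.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    library = library or MotifLibrary.default()
    rng = _as_rng(rng_seed)
    pool = library.core_motifs if label == 1 else library.negative_pool
    k = int(rng.integers(3, 6))
    draws = [pool[int(i)] for i in rng.integers(0, len(pool), size=k)]
    if sum(m.width for m in draws) > length:
        raise ValueError("sampled motif widths exceed sequence length")
    placed = _place_motifs(draws, length, rng)

    probs = np.full((length, 4), 0.25)
    placements: list[tuple[str, int, int]] = []
    for motif, start in placed:
        probs[start : start + motif.width] = motif.probs
        placements.append((motif.name, start, start + motif.width))

    u = rng.random(length)
    cum = probs.cumsum(axis=1)
    letters = (u[:, None] > cum).sum(axis=1)
    onehot = np.zeros((length, 4), dtype=np.float32)
    onehot[np.arange(length), letters] = 1.0

    return AnnotatedSequence(
        onehot=onehot,
        label=label,
        ground_truth=GroundTruthMatrix(probs=probs),
        motif_placements=placements,
        sequence_id=sequence_id,
    )


def generate_dataset(
    n: int = 20_000,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    library: MotifLibrary | None = None,
    seed: int = 0,
    length: int = DEFAULT_LENGTH,
) -> DatasetSplits:
    """Generate a balanced dataset and split it into train/valid/test.

    Exactly n/2 positive and n/2 negative sequences are drawn; the single
    ``seed`` fans out to independent per-sequence streams, so generation is
    reproducible (byte-identical) regardless of iteration order.  Splits are
    stratified by class, so |#pos - #neg| <= 1 in every split.
    """
    if n % 2:
        raise ValueError("n must be even for balanced classes")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError(f"split fractions must be non-negative and sum to 1, got {fractions}")
    library = library or MotifLibrary.default()

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n + 1)
    sequences = []
    for i in range(n):
        label = 1 if i < n // 2 else 0
        sequences.append(
            sample_sequence(
                label,
                library,
                length=length,
                rng_seed=np.random.default_rng(child_seeds[i]),
                sequence_id=f"seq{i:06d}",
            )
        )

    split_rng = np.random.default_rng(child_seeds[n])
    pos = [s for s in sequences if s.label == 1]
    neg = [s for s in sequences if s.label == 0]
    split_rng.shuffle(pos)
    split_rng.shuffle(neg)

    def cut(items: list) -> tuple[list, list, list]:
        n_tr = int(round(len(items) * fractions[0]))
        n_va = int(round(len(items) * fractions[1]))
        return items[:n_tr], items[n_tr : n_tr + n_va], items[n_tr + n_va :]

    parts = [cut(pos), cut(neg)]
    splits = []
    for j in range(3):
        merged = parts[0][j] + parts[1][j]
        split_rng.shuffle(merged)
        splits.append(merged)
    return DatasetSplits(
        train=splits[0], valid=splits[1], test=splits[2], fractions=fractions, seed=seed
    )


def write_dataset(splits: DatasetSplits, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset to disk: FASTA + BED + ground-truth arrays per split.

    FASTA headers carry the sequence id and label (``>seq000001 label=1``);
    BED intervals are 0-based half-open with the motif id in the name column;
    ground-truth matrices, labels and ids go into one ``.npz`` per split.
    """
    from . import io as sgio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name in ("train", "valid", "test"):
        seqs = splits.split(name)
        fa = out / f"{name}.fa"
        bed = out / f"{name}_motifs.bed"
        npz = out / f"{name}_ground_truth.npz"
        sgio.write_fasta(seqs, fa)
        sgio.write_bed(seqs, bed)
        probs = (
            np.stack([s.ground_truth.probs for s in seqs]) if seqs else np.zeros((0, 0, 4))
        )
        np.savez(
            npz,
            probs=probs,
            ids=np.array([s.sequence_id for s in seqs], dtype=str),
            labels=np.array([s.label for s in seqs], dtype=int),
            alphabet=np.array(DNA_ALPHABET),
        )
        written.update({f"{name}_fasta": fa, f"{name}_bed": bed, f"{name}_ground_truth": npz})
    meta = out / "dataset.yaml"
    meta.write_text(
        yaml.safe_dump(
            {
                "fractions": list(splits.fractions),
                "seed": splits.seed,
                "sizes": {k: len(splits.split(k)) for k in ("train", "valid", "test")},
            }
        )
    )
    written["meta"] = meta
    return written


def read_dataset(in_dir: str | Path) -> DatasetSplits:
    """Reconstruct :class:`DatasetSplits` written by :func:`write_dataset`."""
    from . import io as sgio

    src = Path(in_dir)
    meta = yaml.safe_load((src / "dataset.yaml").read_text())
    out: dict[str, list[AnnotatedSequence]] = {}
    for name in ("train", "valid", "test"):
        records = sgio.read_fasta(src / f"{name}.fa")
        placements = sgio.read_bed(src / f"{name}_motifs.bed")
        with np.load(src / f"{name}_ground_truth.npz") as z:
            probs, ids, labels = z["probs"], z["ids"], z["labels"]
        id_to_row = {str(i): k for k, i in enumerate(ids)}
        seqs = []
        for seq_id, label, seq_str in records:
            row = id_to_row[seq_id]
            if int(labels[row]) != label:
                raise ValueError(f"label mismatch for {seq_id} between FASTA and arrays")
            seqs.append(
                AnnotatedSequence(
                    onehot=onehot_from_string(seq_str),
                    label=label,
                    ground_truth=GroundTruthMatrix(probs=probs[row]),
                    motif_placements=placements.get(seq_id, []),
                    sequence_id=seq_id,
                )
            )
        out[name] = seqs
    return DatasetSplits(
        train=out["train"],
        valid=out["valid"],
        test=out["test"],
        fractions=tuple(meta["fractions"]),
        seed=int(meta["seed"]),
    )
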