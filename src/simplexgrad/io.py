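"""File formats: FASTA/BED for sequences, array containers and TSV for attribution maps.

Attribution maps travel either as an ``.npz`` container with named datasets
(``scores`` (N, L, A), ``ids``, ``alphabet``) or as long-format TSV with
columns sequence_id, position, category, score.  Positions are 0-based;
BED intervals are 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DNA_ALPHABET, AttributionMap


def write_fasta(sequences, path: str | Path) -> None:
    """Write annotated sequences; the label rides in the description (``label=1``)."""
    records = [
        SeqRecord(Seq(s.string), id=s.sequence_id, description=f"label={s.label}")
        for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, int, str]]:
    """Return (sequence_id, label, sequence string) per record; label -1 if absent."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = -1
        for token in rec.description.split():
            if token.startswith("label="):
                label = int(token.split("=", 1)[1])
        out.append((rec.id, label, str(rec.seq).upper()))
    return out


def read_fasta_onehot(path: str | Path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a FASTA of equal-length sequences as a stacked one-hot array."""
    from .synthetic import onehot_from_string

    records = read_fasta(path)
    if not records:
        raise ValueError(f"no sequences in {path}")
    X = np.stack([onehot_from_string(seq) for _, _, seq in records])
    ids = [rid for rid, _, _ in records]
    labels = np.array([lab for _, lab, _ in records])
    return X, ids, labels


def write_bed(sequences, path: str | Path) -> None:
    rows = [
        (s.sequence_id, start, end, motif_id)
        for s in sequences
        for motif_id, start, end in s.motif_placements
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Map sequence id -> list of (motif id, start, end)."""
    path = Path(path)
    out: dict[str, list[tuple[str, int, int]]] = {}
    if path.stat().st_size == 0:
        return out
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append((str(row.name), int(row.start), int(row.end)))
    return out


def write_attribution_npz(
    maps: Iterable[AttributionMap] | np.ndarray,
    path: str | Path,
    ids: list[str] | None = None,
    alphabet=DNA_ALPHABET,
) -> None:
    if isinstance(maps, np.ndarray):
        scores = np.asarray(maps, dtype=float)
        if scores.ndim == 2:
            scores = scores[None]
        ids = ids or [f"map{i:06d}" for i in range(scores.shape[0])]
    else:
        maps = list(maps)
        scores = np.stack([m.scores for m in maps])
        ids = ids or [m.sequence_id or f"map{i:06d}" for i, m in enumerate(maps)]
        alphabet = maps[0].alphabet
    np.savez(path, scores=scores, ids=np.array(ids), alphabet=np.array(alphabet))


def read_attribution_npz(path: str | Path) -> list[AttributionMap]:
    with np.load(str(path)) as z:
        scores, ids, alphabet = z["scores"], z["ids"], tuple(str(a) for a in z["alphabet"])
    return [
        AttributionMap(scores=scores[i], alphabet=alphabet, sequence_id=str(ids[i]))
        for i in range(scores.shape[0])
    ]


def write_attribution_tsv(maps: Iterable[AttributionMap], path: str | Path) -> None:
    """Long format: sequence_id, position (0-based), category, score."""
    frames = []
    for m in maps:
        L, A = m.scores.shape
        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": np.repeat(m.sequence_id, L * A),
                    "position": np.repeat(np.arange(L), A),
                    "category": np.tile(list(m.alphabet), L),
                    "score": m.scores.reshape(-1),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_attribution_tsv(path: str | Path) -> list[AttributionMap]:
    df = pd.read_csv(path, sep="\t")
    required = {"sequence_id", "position", "category", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"attribution TSV must have columns {sorted(required)}")
    maps = []
    for seq_id, grp in df.groupby("sequence_id", sort=False):
        alphabet = tuple(dict.fromkeys(grp["category"]))
        L = int(grp["position"].max()) + 1
        scores = np.full((L, len(alphabet)), np.nan)
        cat_idx = {c: i for i, c in enumerate(alphabet)}
        scores[grp["position"].to_numpy(), [cat_idx[c] for c in grp["category"]]] = grp[
            "score"
        ].to_numpy()
        if np.isnan(scores).any():
            raise ValueError(f"incomplete attribution record for sequence {seq_id!r}")
        maps.append(AttributionMap(scores=scores, alphabet=alphabet, sequence_id=str(seq_id)))
    return maps


def read_attributions(path: str | Path) -> list[AttributionMap]:
    """Dispatch on extension: ``.npz`` container or ``.tsv`` long format."""
    path = Path(path)
    if path.suffix == ".npz":
        return read_attribution_npz(path)
    return read_attribution_tsv(path)


def write_attributions(maps: list[AttributionMap], path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        write_attribution_npz(maps, path)
    else:
        write_attribution_tsv(maps, path)
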