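"""Position frequency matrices for the synthetic motif benchmark.

The benchmark embeds five transcription-factor core motifs — CEBPB, GABPA,
MAX, SP1 and YY1 — plus their reverse complements into random DNA.  The
embedded PFMs here are synthetic: they are constructed from the published
consensus binding sites of these factors (bZIP TTGCGCAA, ETS CCGGAAGT,
E-box CACGTG, GC-box GGGGCGGGG, YY1 CGCCATTTT), not copied from a motif
database, and are shaped to have realistic information-content profiles
(strong cores, softer flanks).  A loader for user-supplied JASPAR- or
MEME-format PFM files is provided so real database matrices can be swapped
in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import DNA_ALPHABET

_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}

# IUPAC degeneracy -> set of allowed bases
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PFM:
    """A position frequency matrix: (width, 4) rows of nucleotide probabilities."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PFM {self.name!r} must have shape (width, 4)")
        if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PFM {self.name!r} columns must be probability vectors")
        object.__setattr__(self, "probs", probs / probs.sum(axis=1, keepdims=True))

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PFM":
        """Reverse position order and swap A<->T, C<->G (a flip of both axes in ACGT order)."""
        return PFM(name=self.name + "_rc", probs=self.probs[::-1, ::-1].copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, PFM) and self.name == other.name and np.array_equal(
            self.probs, other.probs
        )

    def __hash__(self) -> int:
        return hash((self.name, self.probs.tobytes()))


def pfm_from_consensus(name: str, consensus: str, strength: float = 0.88) -> PFM:
    """Build a PFM from an IUPAC consensus string.

    Lowercase letters denote soft (flank) positions with reduced preference;
    uppercase letters get probability ``strength`` split over the allowed
    bases, the remainder spread over the rest.
    """
    rows = []
    for ch in consensus:
        soft = ch.islower()
        bases = _IUPAC[ch.upper()]
        p_major = (0.55 if soft else strength)
        row = np.full(4, (1.0 - p_major) / (4 - len(bases))) if len(bases) < 4 else np.full(4, 0.25)
        if len(bases) < 4:
            for b in bases:
                row[_BASE_INDEX[b]] = p_major / len(bases)
        rows.append(row)
    return PFM(name=name, probs=np.array(rows))


# Core motifs, from the canonical consensus sites of the five factors.
_CORE_CONSENSUS = {
    "CEBPB": "aTTGCGCAAt",
    "GABPA": "aCCGGAAGTg",
    "MAX": "aaCACGTGtt",
    "SP1": "gGGGGCGGGGc",
    "YY1": "gCGCCATTTTg",
}

# Background motifs shaped on consensus sites of unrelated factors; these
# dilute the negative-class pool so negatives rarely assemble a positive
# regulatory code by chance.
_BACKGROUND_CONSENSUS = {
    "GATA": "aGATAAGa",
    "TBP": "TATAAAag",
    "NFKB": "GGGACTTTCC",
    "AP1": "tTGACTCAt",
    "CREB": "tTGACGTCAt",
    "MEF2": "cTAAAAATAg",
    "SRF": "gCCATATATGG",
    "OCT": "aTGCAAAT",
    "SOX": "aACAATGg",
    "FOXA": "tGTTTACtt",
    "NRF1": "gCGCATGCGc",
    "RUNX": "aTGTGGTTt",
    "TEAD": "aGGAATGt",
    "IRF": "aAANTGAAAg",
    "STAT": "tTTCCCGGAAa",
    "ELK": "aCTTCCGGt",
    "KLF": "aAAAGGGGGc",
    "ZEB": "cCACCTGt",
    "RFX": "gTTGCCATGGcaac",
    "HSF": "aGAANNTTCt",
    "PAX": "tTCACGCttga",
    "ESRRB": "tCAAGGTCAc",
    "CTCFL": "cCACCAGGGGGc",
    "SNAI": "cAGGTGct",
}


@dataclass
class MotifLibrary:
    """Motif pools for the billboard benchmark.

    ``core_motifs`` holds the 5 factor PFMs and their reverse complements
    (10 total) — the regulatory code of the positive class.  The negative
    class draws from ``core_motifs + background_motifs``, so negatives may
    contain core motifs but are unlikely to assemble a positive combination.
    """

    core_motifs: list[PFM] = field(default_factory=list)
    background_motifs: list[PFM] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.core_motifs) & set(self.background_motifs):
            raise ValueError("core and background motif sets must be disjoint")

    @property
    def negative_pool(self) -> list[PFM]:
        return self.core_motifs + self.background_motifs

    @property
    def by_name(self) -> dict[str, PFM]:
        return {m.name: m for m in self.negative_pool}

    @classmethod
    def default(cls, n_background: int = 100) -> "MotifLibrary":
        """The built-in library: 10 core PFMs (5 + reverse complements) and 100 background PFMs.

        The first 24 background PFMs come from the consensus table above;
        the remainder are procedurally generated (fixed seed) random-consensus
        motifs of width 7-13, so the negative-class pool is large enough that
        core motifs are rare draws for negatives.
        """
        core: list[PFM] = []
        for name, cons in _CORE_CONSENSUS.items():
            fwd = pfm_from_consensus(name, cons)
            core.append(fwd)
            core.append(fwd.reverse_complement())
        background = [pfm_from_consensus(n, c) for n, c in _BACKGROUND_CONSENSUS.items()]
        if n_background < 1:
            raise ValueError("n_background must be >= 1")
        rng = np.random.default_rng(np.random.SeedSequence(20230509))
        while len(background) < n_background:
            width = int(rng.integers(7, 14))
            letters = rng.integers(0, 4, size=width)
            cons = "".join(
                "ACGT"[b] if rng.random() < 0.75 else "ACGT"[b].lower() for b in letters
            )
            pfm = pfm_from_consensus(f"BG{len(background):03d}", cons)
            if pfm not in core and pfm not in background:
                background.append(pfm)
        return cls(core_motifs=core, background_motifs=background[:n_background])


def load_pfms(path: str | Path) -> list[PFM]:
    """Read PFMs from a JASPAR- or MEME-format text file (auto-detected).

    JASPAR: ``>ID NAME`` header followed by four ``A [ .. ]`` count rows.
    MEME: minimal format with ``letter-probability matrix`` blocks.
    Counts are normalized to probabilities per position.
    """
    text = Path(path).read_text()
    if "letter-probability matrix" in text:
        return _parse_meme(text)
    return _parse_jaspar(text)


def _parse_jaspar(text: str) -> list[PFM]:
    pfms: list[PFM] = []
    name = None
    rows: dict[str, list[float]] = {}
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if name is not None and len(rows) == 4:
                mat = np.array([rows[b] for b in DNA_ALPHABET]).T
                pfms.append(PFM(name=name, probs=mat / mat.sum(axis=1, keepdims=True)))
            parts = line[1:].split()
            name = parts[-1] if parts else None
            rows = {}
        elif line and line[0] in "ACGT":
            base = line[0]
            nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", line[1:])
            rows[base] = [float(v) for v in nums]
    if not pfms:
        raise ValueError("no PFM records found in JASPAR input")
    return pfms


def _parse_meme(text: str) -> list[PFM]:
    pfms: list[PFM] = []
    lines = text.splitlines()
    i = 0
    name = None
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif{len(pfms)}"
        elif line.startswith("letter-probability matrix"):
            m = re.search(r"w=\s*(\d+)", line)
            rows = []
            i += 1
            while i < len(lines):
                vals = lines[i].split()
                if len(vals) == 4:
                    rows.append([float(v) for v in vals])
                    i += 1
                    if m and len(rows) == int(m.group(1)):
                        break
                else:
                    break
            i -= 1
            pfms.append(PFM(name=name or f"motif{len(pfms)}", probs=np.array(rows)))
            name = None
        i += 1
    if not pfms:
        raise ValueError("no PFM records found in MEME input")
    return pfms
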