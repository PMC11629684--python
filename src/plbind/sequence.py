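"""Per-residue sequence embeddings from a pluggable frozen backend.

The default backend is a deterministic lightweight embedder: each
residue letter maps to a fixed random vector (seeded by a stable hash of
the letter), optionally mixed with a local sliding window so nearby
residues share context.  It is frozen by construction — it holds no
trainable parameters — and exists so the full pipeline runs without any
downloaded language model.  A pretrained transformer backend can be
plugged in through the same interface; its weights are never updated by
training (the frozen contract applies to every backend).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = ["SequenceEmbedding", "FallbackEmbedder", "ProtBertEmbedder", "embed_sequence", "read_fasta"]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SequenceEmbedding:
    tokens: np.ndarray  # (length, width)
    sequence: str

    @property
    def length(self) -> int:
        return self.tokens.shape[0]

    @property
    def width(self) -> int:
        return self.tokens.shape[1]


class FallbackEmbedder:
    """Hash-seeded per-residue lookup with local window mixing.

    ``window = 0`` makes the embedding strictly positional-independent:
    changing one residue changes exactly one row.
    """

    name = "fallback"

    def __init__(self, width: int = 32, window: int = 2, seed: int = 0):
        self.width = width
        self.window = window
        self.seed = seed
        self._table: dict[str, np.ndarray] = {}

    def _vector(self, letter: str) -> np.ndarray:
        if letter not in self._table:
            h = zlib.crc32(letter.encode()) ^ (self.seed & 0x7FFFFFFF)
            rng = np.random.default_rng(h)
            self._table[letter] = rng.standard_normal(self.width)
        return self._table[letter]

    def __call__(self, sequence: str) -> np.ndarray:
        base = np.stack([self._vector(aa) for aa in sequence])
        if self.window <= 0 or len(sequence) == 1:
            return base
        # centered moving average over +-window residues
        n = base.shape[0]
        out = np.empty_like(base)
        for i in range(n):
            lo, hi = max(0, i - self.window), min(n, i + self.window + 1)
            out[i] = base[lo:hi].mean(axis=0)
        return out


class ProtBertEmbedder:
    """Optional pretrained protein-language-model backend (frozen).

    Requires the ``transformers`` package and downloaded weights, neither
    of which is bundled; constructing it without them raises.  Per-residue
    hidden states (width 1024) are returned, special tokens stripped.
    """

    name = "protbert"
    width = 1024

    def __init__(self, model_name: str = "Rostlab/prot_bert"):
        try:
            from transformers import BertModel, BertTokenizer  # type: ignore
        except ImportError as err:  # pragma: no cover - optional path
            raise ImportError(
                "the pretrained sequence backend requires the 'transformers' "
                "package and downloaded weights; use the fallback backend instead"
            ) from err
        self._tok = BertTokenizer.from_pretrained(model_name, do_lower_case=False)  # pragma: no cover
        self._model = BertModel.from_pretrained(model_name).eval()  # pragma: no cover

    def __call__(self, sequence: str) -> np.ndarray:  # pragma: no cover - optional path
        import torch  # type: ignore

        with torch.no_grad():
            ids = self._tok(" ".join(sequence), return_tensors="pt")
            out = self._model(**ids).last_hidden_state[0, 1:-1]
        return out.double().numpy()


def embed_sequence(
    sequence: str,
    backend: FallbackEmbedder | ProtBertEmbedder,
    chunk: int = 1000,
    overlap: int = 50,
) -> SequenceEmbedding:
    """Embed an amino-acid sequence with the given frozen backend.

    Unknown characters map to ``X`` (warned).  Sequences longer than
    ``chunk`` are embedded in overlapping windows whose overlaps are
    averaged, so arbitrarily long chains stay within backend limits.
    """
    if not sequence:
        raise ValueError("empty sequence")
    cleaned = []
    for ch in sequence.upper():
        if ch in STANDARD_AA or ch == "X":
            cleaned.append(ch)
        else:
            import logging

            logging.getLogger(__name__).warning("unknown residue %r mapped to X", ch)
            cleaned.append("X")
    seq = "".join(cleaned)

    if len(seq) <= chunk:
        tokens = backend(seq)
    else:
        width = backend(seq[:1]).shape[1]
        acc = np.zeros((len(seq), width))
        count = np.zeros(len(seq))
        start = 0
        while start < len(seq):
            stop = min(start + chunk, len(seq))
            piece = backend(seq[start:stop])
            acc[start:stop] += piece
            count[start:stop] += 1
            if stop == len(seq):
                break
            start = stop - overlap
        tokens = acc / count[:, None]
    return SequenceEmbedding(tokens=tokens, sequence=seq)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence} (standalone use)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
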