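"""Overlapping k-mer tokenization with BERT-style chunking.

A DNA sequence of length n yields the n-k+1 stride-1 k-mers as tokens.
Token streams longer than 510 are cut into consecutive 510-token segments;
each segment is wrapped [CLS]...[SEP] and right-padded with [PAD] to a
fixed encoder window of 512 positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

MAX_POSITIONS = 512
CONTENT_PER_CHUNK = MAX_POSITIONS - 2  # room left by [CLS] and [SEP]

PAD, UNK, CLS, SEP, MASK = "[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]"
SPECIALS = (PAD, UNK, CLS, SEP, MASK)
PAD_ID, UNK_ID, CLS_ID, SEP_ID, MASK_ID = range(5)

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class Vocabulary:
    """Token index map over all 4^k k-mers plus the five special tokens.

    Specials occupy the reserved low indices ([PAD]=0, [UNK]=1, [CLS]=2,
    [SEP]=3, [MASK]=4); k-mers follow in lexicographic order.
    """

    k: int
    token_to_id: dict[str, int]

    @classmethod
    def build(cls, k: int) -> "Vocabulary":
        if not 3 <= k <= 6:
            raise ValueError(f"k must be in 3..6, got {k}")
        mapping = {tok: i for i, tok in enumerate(SPECIALS)}
        for i, kmer in enumerate(itertools.product(_ALPHABET, repeat=k)):
            mapping["".join(kmer)] = len(SPECIALS) + i
        return cls(k=k, token_to_id=mapping)

    def __len__(self) -> int:
        return len(self.token_to_id)

    def encode(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)

    def id_to_token(self) -> dict[int, str]:
        return {i: t for t, i in self.token_to_id.items()}

    def save(self, path: str | Path) -> None:
        """One token per line, line number == index."""
        inv = self.id_to_token()
        with open(path, "w") as fh:
            for i in range(len(inv)):
                fh.write(inv[i] + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        with open(path) as fh:
            tokens = [line.rstrip("\n") for line in fh if line.strip()]
        if tuple(tokens[:5]) != SPECIALS:
            raise ValueError(f"{path}: special tokens missing or reordered")
        k = len(tokens[5])
        vocab = cls(k=k, token_to_id={t: i for i, t in enumerate(tokens)})
        if len(vocab) != 4**k + 5:
            raise ValueError(f"{path}: expected {4**k + 5} tokens, found {len(vocab)}")
        return vocab


@dataclass
class TokenizedDoc:
    """One sequence as fixed-width encoder chunks.

    ``chunks`` is (n_chunks, 512) int token ids, ``attention_masks`` the
    parallel 0/1 matrix (1 exactly on non-[PAD] positions), and
    ``n_content_tokens`` the total k-mer count across chunks.
    """

    seq_id: str
    chunks: np.ndarray
    attention_masks: np.ndarray
    n_content_tokens: int

    @property
    def n_chunks(self) -> int:
        return self.chunks.shape[0]

    def chunk_content_lengths(self) -> np.ndarray:
        """Number of content (k-mer) tokens per chunk."""
        return self.attention_masks.sum(axis=1) - 2


def kmer_tokenize(seq: str, k: int) -> list[str]:
    """Split ``seq`` into its overlapping stride-1 k-mers.

    k-mers containing a character outside {A,C,G,T} become [UNK]; this keeps
    the token count (and hence coordinates) identical to the clean case.
    """
    if not 3 <= k <= 6:
        raise ValueError(f"k must be in 3..6, got {k}")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    tokens = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        tokens.append(kmer if set(kmer) <= set(_ALPHABET) else UNK)
    return tokens


def chunk_and_pad(tokens: list[str], vocab: Vocabulary, seq_id: str = "") -> TokenizedDoc:
    """Wrap a token stream into padded 512-wide encoder chunks.

    Consecutive 510-token segments (no overlap; last one may be short), each
    framed as [CLS] content [SEP] and right-padded with [PAD].
    """
    if not tokens:
        raise ValueError("empty token list")
    n = len(tokens)
    n_chunks = (n + CONTENT_PER_CHUNK - 1) // CONTENT_PER_CHUNK
    chunks = np.full((n_chunks, MAX_POSITIONS), PAD_ID, dtype=np.int64)
    masks = np.zeros((n_chunks, MAX_POSITIONS), dtype=np.int64)
    for c in range(n_chunks):
        seg = tokens[c * CONTENT_PER_CHUNK : (c + 1) * CONTENT_PER_CHUNK]
        ids = [CLS_ID] + [vocab.encode(t) for t in seg] + [SEP_ID]
        chunks[c, : len(ids)] = ids
        masks[c, : len(ids)] = 1
    return TokenizedDoc(
        seq_id=seq_id, chunks=chunks, attention_masks=masks, n_content_tokens=n
    )


def tokenize_document(seq: str, vocab: Vocabulary, seq_id: str = "") -> TokenizedDoc:
    """Convenience: k-mer tokenize then chunk and pad."""
    return chunk_and_pad(kmer_tokenize(seq, vocab.k), vocab, seq_id=seq_id)


def detokenize(doc: TokenizedDoc, vocab: Vocabulary) -> str:
    """Reconstruct the original sequence from a TokenizedDoc.

    Overlapping k-mers are merged (first token verbatim, then the last base
    of each subsequent token); exact when no [UNK] occurred.
    """
    inv = vocab.id_to_token()
    tokens: list[str] = []
    for c in range(doc.n_chunks):
        row = doc.chunks[c]
        mask = doc.attention_masks[c].astype(bool)
        content = row[mask][1:-1]  # strip [CLS] and [SEP]
        tokens.extend(inv[int(i)] for i in content)
    if any(t == UNK for t in tokens):
        raise ValueError("cannot detokenize: stream contains [UNK]")
    if not tokens:
        return ""
    seq = tokens[0]
    for t in tokens[1:]:
        seq += t[-1]
    return seq
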