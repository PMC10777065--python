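"""Sequence and interaction-table I/O, dataset assembly and negative sampling.

Interacting circRNA/miRNA pairs come as a two-column edge list; only
positive (experimentally supported) pairs are observed, so the negative
class is drawn uniformly from the unobserved part of the bipartite pair
space, one negative per positive by default. Every constructed dataset is
persisted together with the sampling seed so an experiment can be re-run
bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


class Role(str, Enum):
    """Which side of the bipartite interaction a molecule sits on."""

    CIRC = "circRNA"
    MIR = "miRNA"


@dataclass(frozen=True)
class SequenceRecord:
    """A single RNA molecule, stored as DNA (U already mapped to T)."""

    id: str
    role: Role
    seq: str

    def usable(self, k: int) -> bool:
        """True if the sequence is long enough to yield at least one k-mer."""
        return len(self.seq) >= k


@dataclass
class InteractionSet:
    """Labelled (circ_id, mir_id) pairs with sampling provenance.

    ``provenance`` maps each pair to ``"observed"`` (from the edge list) or
    ``"sampled"`` (generated negative); ``seed`` is the negative-sampling seed.
    """

    pairs: list[tuple[str, str, int]]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        keys = [(c, m) for c, m, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (circ_id, mir_id) pair in InteractionSet")
        for _, _, lab in self.pairs:
            if lab not in (0, 1):
                raise ValueError(f"label must be 0 or 1, got {lab!r}")

    @property
    def positives(self) -> list[tuple[str, str]]:
        return [(c, m) for c, m, lab in self.pairs if lab == 1]

    @property
    def negatives(self) -> list[tuple[str, str]]:
        return [(c, m) for c, m, lab in self.pairs if lab == 0]

    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=np.int64)


def _normalize_seq(raw: str) -> str:
    """Uppercase and reverse-transcribe (U -> T). Other characters are kept
    verbatim; the tokenizer maps any k-mer containing them to [UNK] so that
    sequence coordinates are preserved."""
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path, role: Role) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords with the given role.

    Ids are the header token up to the first whitespace. Duplicate ids are an
    error because downstream feature tables are keyed by id.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if not rid:
            raise ValueError(f"{path}: FASTA entry with empty id")
        if rid in seen:
            raise ValueError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(id=rid, role=role, seq=_normalize_seq(str(entry.seq))))
    return records


def read_edge_list(path: str | Path, delimiter: str | None = None) -> list[tuple[str, str]]:
    """Read a two-column (circ_id, mir_id) edge list.

    The delimiter is auto-detected among tab and comma unless given.
    Duplicate rows are dropped (count logged); order of first appearance is
    preserved.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            delim = delimiter
            if delim is None:
                delim = "\t" if "\t" in line else ","
            fields = [f.strip() for f in line.split(delim)]
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                )
            pair = (fields[0], fields[1])
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            pairs.append(pair)
    if n_dup:
        logger.info("read_edge_list(%s): dropped %d duplicate pairs", path, n_dup)
    return pairs


def sample_negatives(
    positives: Sequence[tuple[str, str]],
    n: int,
    circ_ids: Sequence[str],
    mir_ids: Sequence[str],
    seed: int,
) -> list[tuple[str, str]]:
    """Draw ``n`` distinct non-interacting (circ, mir) pairs uniformly.

    Each draw picks one circRNA and one miRNA at random and keeps the pair if
    it is neither a positive nor a previously drawn negative. When ``n`` is a
    large fraction of the available complement the rejection loop is replaced
    by an exact without-replacement draw over the enumerated complement; both
    routes are deterministic under ``seed``.
    """
    pos = set(positives)
    space = len(circ_ids) * len(mir_ids)
    avail = space - len(pos)
    if n > avail:
        raise ValueError(f"cannot sample {n} negatives from a complement of size {avail}")
    rng = np.random.default_rng(seed)
    if n > avail // 2:
        complement = [
            (c, m) for c in circ_ids for m in mir_ids if (c, m) not in pos
        ]
        idx = rng.choice(len(complement), size=n, replace=False)
        return [complement[i] for i in idx]
    chosen: list[tuple[str, str]] = []
    taken: set[tuple[str, str]] = set()
    while len(chosen) < n:
        c = circ_ids[int(rng.integers(len(circ_ids)))]
        m = mir_ids[int(rng.integers(len(mir_ids)))]
        if (c, m) in pos or (c, m) in taken:
            continue
        taken.add((c, m))
        chosen.append((c, m))
    return chosen


def build_interaction_set(
    positives: Sequence[tuple[str, str]],
    circ_ids: Sequence[str],
    mir_ids: Sequence[str],
    seed: int,
    n_negatives: int | None = None,
) -> InteractionSet:
    """Assemble the balanced labelled dataset: observed positives plus
    ``n_negatives`` sampled negatives (defaults to one per positive)."""
    known_c, known_m = set(circ_ids), set(mir_ids)
    for c, m in positives:
        if c not in known_c:
            raise KeyError(f"positive pair references unknown circRNA id {c!r}")
        if m not in known_m:
            raise KeyError(f"positive pair references unknown miRNA id {m!r}")
    n_neg = len(positives) if n_negatives is None else n_negatives
    negatives = sample_negatives(positives, n_neg, list(circ_ids), list(mir_ids), seed)
    pairs = [(c, m, 1) for c, m in positives] + [(c, m, 0) for c, m in negatives]
    prov = {(c, m): "observed" for c, m in positives}
    prov.update({(c, m): "sampled" for c, m in negatives})
    return InteractionSet(pairs=pairs, provenance=prov, seed=seed)


def write_interaction_set(dataset: InteractionSet, path: str | Path) -> None:
    """Persist a dataset as three-column TSV plus a JSON sidecar with the seed."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("circ_id\tmir_id\tlabel\n")
        for c, m, lab in dataset.pairs:
            fh.write(f"{c}\t{m}\t{lab}\n")
    sidecar = {
        "seed": dataset.seed,
        "n_positive": len(dataset.positives),
        "n_negative": len(dataset.negatives),
        "provenance": {f"{c}\t{m}": v for (c, m), v in dataset.provenance.items()},
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_interaction_set(path: str | Path) -> InteractionSet:
    """Inverse of :func:`write_interaction_set` (exact round-trip)."""
    path = Path(path)
    pairs: list[tuple[str, str, int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["circ_id", "mir_id", "label"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            pairs.append((fields[0], fields[1], int(fields[2])))
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    seed = None
    prov: dict[tuple[str, str], str] = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        seed = meta.get("seed")
        for key, v in meta.get("provenance", {}).items():
            c, m = key.split("\t")
            prov[(c, m)] = v
    return InteractionSet(pairs=pairs, provenance=prov, seed=seed)


def write_feature_table(
    ids: Iterable[str], matrix: np.ndarray, path: str | Path, prefix: str = "f"
) -> None:
    """Export an (id x feature) matrix as TSV: id column then numbered columns."""
    ids = list(ids)
    matrix = np.asarray(matrix)
    if matrix.shape[0] != len(ids):
        raise ValueError("row count does not match number of ids")
    with open(path, "w") as fh:
        cols = "\t".join(f"{prefix}{j}" for j in range(matrix.shape[1]))
        fh.write(f"id\t{cols}\n")
        for rid, row in zip(ids, matrix):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{rid}\t{vals}\n")


def read_feature_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    return ids, np.array(rows, dtype=np.float64)
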