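"""Download-free synthetic fixtures with learnable planted structure.

The generator miniaturizes the geometry of a real circRNA-miRNA
interaction compendium (a few thousand molecules, ~1:4 miRNA:circRNA
ratio, ~10k positive pairs) into a CI-sized instance with two planted,
independent signals:

* network signal -- circRNAs and miRNAs are assigned to blocks and
  positive edges are drawn Bernoulli(p_in) within a block and
  Bernoulli(p_out) across blocks, so a structural embedding can separate
  interacting from non-interacting pairs when p_in >> p_out;
* sequence signal -- each block owns a distinct (circRNA-motif,
  miRNA-motif) pair implanted (with probability ``motif_fidelity``) into
  the sequences of block members that touch a positive edge, over an
  i.i.d. uniform ACGT background, so a sequence model can recover block
  identity from sequence alone.

Setting p_in = p_out removes the network signal and motif_fidelity = 0
removes the sequence signal; with both removed the task is unlearnable by
construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .io_corpus import Role, SequenceRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults give ~120x60 nodes in 4 blocks and ~800 positive edges, with
    sequence lengths short enough that a single implanted motif is a
    noticeable fraction of the k-mer stream.
    """

    n_circ: int = 120
    n_mir: int = 60
    n_blocks: int = 4
    p_in: float = 0.45
    p_out: float = 0.005
    circ_len_range: tuple[int, int] = (100, 200)
    mir_len_range: tuple[int, int] = (20, 28)
    motif_len: int = 12
    motif_fidelity: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.p_in == 0.0:
            raise ValueError("p_in must be positive")
        if not 0.0 <= self.motif_fidelity <= 1.0:
            raise ValueError("motif_fidelity must be in [0, 1]")
        for lo, hi in (self.circ_len_range, self.mir_len_range):
            if lo > hi or lo < self.motif_len:
                raise ValueError("length ranges must contain motif_len and be ordered")
        if self.n_blocks < 1 or self.n_circ < self.n_blocks or self.n_mir < self.n_blocks:
            raise ValueError("each block needs at least one node of each kind")


@dataclass
class Fixture:
    """Generated dataset plus ground truth for diagnostics."""

    spec: FixtureSpec
    circ_records: list[SequenceRecord]
    mir_records: list[SequenceRecord]
    positive_pairs: list[tuple[str, str]]
    truth: dict


def gen_long_sequence(length: int, seed: int = 0) -> str:
    """Uniform i.i.d. ACGT string of exactly ``length`` bases."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _implant(rng: np.random.Generator, seq: str, motif: str) -> tuple[str, int]:
    pos = int(rng.integers(0, len(seq) - len(motif) + 1))
    return seq[:pos] + motif + seq[pos + len(motif):], pos


def gen_fixture(spec: FixtureSpec) -> Fixture:
    """Generate sequences, positive edge list, and a truth sidecar.

    Blocks are assigned uniformly at random; motifs are implanted only into
    molecules incident to at least one positive edge (non-interacting
    molecules stay pure background).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    circ_ids = [f"circ{i:04d}" for i in range(spec.n_circ)]
    mir_ids = [f"mir{i:04d}" for i in range(spec.n_mir)]
    circ_block = rng.integers(0, spec.n_blocks, size=spec.n_circ)
    mir_block = rng.integers(0, spec.n_blocks, size=spec.n_mir)
    # guarantee every block is populated on both sides
    circ_block[: spec.n_blocks] = np.arange(spec.n_blocks)
    mir_block[: spec.n_blocks] = np.arange(spec.n_blocks)

    same = circ_block[:, None] == mir_block[None, :]
    prob = np.where(same, spec.p_in, spec.p_out)
    edges_mat = rng.random((spec.n_circ, spec.n_mir)) < prob
    positive_pairs = [
        (circ_ids[i], mir_ids[j]) for i, j in np.argwhere(edges_mat)
    ]
    circ_deg = edges_mat.sum(axis=1)
    mir_deg = edges_mat.sum(axis=0)

    motifs = {}
    for b in range(spec.n_blocks):
        motifs[b] = (
            _random_seq(rng, spec.motif_len),
            _random_seq(rng, spec.motif_len),
        )

    def make_records(ids, blocks, degrees, lo, hi, side):
        records, placements = [], {}
        for idx, rid in enumerate(ids):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            if degrees[idx] > 0 and rng.random() < spec.motif_fidelity:
                motif = motifs[int(blocks[idx])][0 if side == "circ" else 1]
                seq, pos = _implant(rng, seq, motif)
                placements[rid] = pos
            records.append(SequenceRecord(
                id=rid, role=Role.CIRC if side == "circ" else Role.MIR, seq=seq))
        return records, placements

    lo, hi = spec.circ_len_range
    circ_records, circ_pos = make_records(circ_ids, circ_block, circ_deg, lo, hi, "circ")
    lo, hi = spec.mir_len_range
    mir_records, mir_pos = make_records(mir_ids, mir_block, mir_deg, lo, hi, "mir")

    truth = {
        "circ_blocks": {cid: int(b) for cid, b in zip(circ_ids, circ_block)},
        "mir_blocks": {mid: int(b) for mid, b in zip(mir_ids, mir_block)},
        "motifs": {str(b): list(pair) for b, pair in motifs.items()},
        "motif_positions": {"circ": circ_pos, "mir": mir_pos},
    }
    return Fixture(
        spec=spec,
        circ_records=circ_records,
        mir_records=mir_records,
        positive_pairs=positive_pairs,
        truth=truth,
    )


def write_fixture(fx: Fixture, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA files, the positive edge list, and the truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "circ_fasta": out / "circ.fasta",
        "mir_fasta": out / "mir.fasta",
        "edges": out / "positive_edges.tsv",
        "truth": out / "truth.json",
    }
    for key, records in (("circ_fasta", fx.circ_records), ("mir_fasta", fx.mir_records)):
        with open(paths[key], "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.seq}\n")
    with open(paths["edges"], "w") as fh:
        for c, m in fx.positive_pairs:
            fh.write(f"{c}\t{m}\n")
    with open(paths["truth"], "w") as fh:
        json.dump({"spec": asdict(fx.spec), **fx.truth}, fh, indent=1)
    return paths
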