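"""Kinase–substrate prediction from consensus phosphorylation motifs.

A consensus motif is a set of allowed residues at offsets around the
phosphoacceptor (offset 0).  Dynamic phosphosites matched by a kinase's
motif propose candidate interactions; candidates are filtered against a
gold-standard network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .graph import topology
from .network import DirectedNetwork

ACCEPTORS = frozenset({"S", "T", "Y"})


@dataclass(frozen=True)
class ConsensusMotif:
    """Position-specific allowed residue sets around the phosphoacceptor."""

    kinase: str
    window: Mapping[int, frozenset[str]]
    pattern: str = ""

    def __post_init__(self) -> None:
        if not self.window:
            raise ValidationError("motif window must be non-empty")
        if 0 not in self.window:
            raise ValidationError("motif must constrain the acceptor (offset 0)")
        if not self.window[0] <= ACCEPTORS:
            raise ValidationError(
                f"acceptor residues must be within {sorted(ACCEPTORS)}, "
                f"got {sorted(self.window[0])}"
            )

    @property
    def acceptors(self) -> frozenset[str]:
        return self.window[0]


@dataclass(frozen=True)
class PhosphositeRecord:
    protein: str
    position: int
    residue: str
    dynamic: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError("phosphosite position is 1-based and >= 1")
        if self.residue not in ACCEPTORS:
            raise ValidationError(
                f"phosphosite residue must be one of {sorted(ACCEPTORS)}"
            )


def parse_motif(kinase: str, pattern: str) -> ConsensusMotif:
    """Parse dash notation like ``R-x-x-S/T`` or ``pS/pT-P`` into a motif.

    Tokens are residue alternatives separated by ``/``; ``x`` is a wildcard
    (the offset is simply unconstrained).  The acceptor position is the
    token carrying a ``p`` prefix, or failing that the first token whose
    residues are all phosphoacceptors (S/T/Y).
    """
    tokens = [t.strip() for t in pattern.strip().split("-")]
    if not tokens or all(t == "" for t in tokens):
        raise FormatError(f"empty motif pattern {pattern!r}")
    parsed: list[frozenset[str] | None] = []
    marked: list[bool] = []
    for tok in tokens:
        if tok.lower() == "x" or tok == "":
            parsed.append(None)
            marked.append(False)
            continue
        residues = set()
        is_marked = False
        for alt in tok.split("/"):
            alt = alt.strip()
            if alt.startswith("p"):
                is_marked = True
                alt = alt[1:]
            if len(alt) != 1 or not alt.isalpha():
                raise FormatError(f"bad residue token {alt!r} in {pattern!r}")
            residues.add(alt.upper())
        parsed.append(frozenset(residues))
        marked.append(is_marked)
    if any(marked):
        acceptor_idx = marked.index(True)
    else:
        acceptor_idx = next(
            (i for i, r in enumerate(parsed) if r is not None and r <= ACCEPTORS),
            -1,
        )
        if acceptor_idx < 0:
            raise FormatError(
                f"no acceptor position (S/T/Y token) found in {pattern!r}"
            )
    window = {
        i - acceptor_idx: residues
        for i, residues in enumerate(parsed)
        if residues is not None
    }
    return ConsensusMotif(kinase=kinase, window=window, pattern=pattern)


def match_motif(motif: ConsensusMotif, sequence: str, position: int) -> bool:
    """True iff every constrained offset around *position* (1-based) matches.

    Offsets that fall outside the sequence fail the match.
    """
    if not 1 <= position <= len(sequence):
        raise ValidationError(
            f"position {position} out of range for sequence of length {len(sequence)}"
        )
    for offset, allowed in motif.window.items():
        idx = position + offset
        if not 1 <= idx <= len(sequence):
            return False
        if sequence[idx - 1].upper() not in allowed:
            return False
    return True


@dataclass(frozen=True)
class PredictionResult:
    edges: frozenset[tuple[str, str]]
    candidates: frozenset[tuple[str, str]]
    n_edges: int
    n_kinases: int
    n_substrates: int


def predict_interactions(
    gold: DirectedNetwork,
    motifs: Iterable[ConsensusMotif],
    phosphosites: Sequence[PhosphositeRecord],
    sequences: Mapping[str, str],
) -> PredictionResult:
    """Propose kinase->substrate edges from motif-matched dynamic sites.

    A kinase with several motifs matches if any of them does (logical OR).
    Retained edges are the candidates present in the gold network's arcs.
    """
    by_kinase: dict[str, list[ConsensusMotif]] = {}
    for m in motifs:
        by_kinase.setdefault(m.kinase, []).append(m)
    if not by_kinase:
        raise ValidationError("no motifs supplied")
    dynamic = [s for s in phosphosites if s.dynamic]
    candidates: set[tuple[str, str]] = set()
    for site in dynamic:
        seq = sequences.get(site.protein)
        if seq is None:
            continue
        for kinase in sorted(by_kinase):
            if kinase == site.protein:
                continue
            if any(match_motif(m, seq, site.position) for m in by_kinase[kinase]):
                candidates.add((kinase, site.protein))
    gold_arcs = topology(gold, drop_self_loops=True).arcs
    retained = frozenset(c for c in candidates if c in gold_arcs)
    return PredictionResult(
        edges=retained,
        candidates=frozenset(candidates),
        n_edges=len(retained),
        n_kinases=len({k for k, _ in retained}),
        n_substrates=len({s for _, s in retained}),
    )


def read_motif_table(path: str | Path) -> list[ConsensusMotif]:
    """TSV with columns kinase, pattern (dash notation)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("kinase", "pattern"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [parse_motif(r.kinase, r.pattern) for r in df.itertuples(index=False)]


def read_phosphosites(path: str | Path) -> list[PhosphositeRecord]:
    """TSV with columns protein, position, residue, dynamic (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("protein", "position", "residue", "dynamic"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            PhosphositeRecord(
                protein=r.protein,
                position=int(r.position),
                residue=r.residue,
                dynamic=r.dynamic in ("1", "true", "True"),
            )
        )
    return records
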