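"""CYP2D6 allele bookkeeping: missense mutation sets, sequence application,
ΔΔG stability classification and heme-proximity annotation of mutation sites.

The built-in table covers the reference allele *1 (no missense mutations) and
the four variants studied alongside it: *14A (P34S, G169R, R296C, S486T),
*51 (R296C, E334A, S486T), *110 (G445R) and *122 (V370I). Positions use
author residue numbering of the mature CYP2D6 sequence.

ΔΔG values (predicted unfolding free-energy change upon mutation, kcal/mol)
are inputs, not predictions made here; the classification rule is that
ΔΔG < 1 kcal/mol indicates a limited effect on protein stability.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MutationError, StructureError
from .structure_io import Structure

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: ΔΔG (kcal/mol) below which a mutation is called limited_effect.
DDG_THRESHOLD_KCAL_MOL = 1.0

#: Minimum residue-to-Fe distance (nm) below which a mutation site is "proximal".
PROXIMITY_CUTOFF_NM = 1.0

_MUTATION_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class Mutation:
    """A single missense substitution, e.g. G445R."""

    wt: str
    pos: int
    mut: str

    def __post_init__(self) -> None:
        if self.wt not in AMINO_ACIDS or self.mut not in AMINO_ACIDS:
            raise ValueError(f"residues must be one of the 20 amino acids: {self}")
        if self.wt == self.mut:
            raise ValueError(f"wild-type and mutant residue are identical: {self}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1: {self}")

    def inverse(self) -> "Mutation":
        return Mutation(wt=self.mut, pos=self.pos, mut=self.wt)

    def __str__(self) -> str:
        return f"{self.wt}{self.pos}{self.mut}"

    @classmethod
    def parse(cls, token: str) -> "Mutation":
        m = _MUTATION_TOKEN.match(token.strip())
        if not m:
            raise ValueError(f"cannot parse mutation token {token!r}")
        return cls(wt=m.group(1), pos=int(m.group(2)), mut=m.group(3))


@dataclass(frozen=True)
class VariantDef:
    """A star allele: name plus its missense mutation set."""

    allele: str
    mutations: frozenset[Mutation] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        positions = [m.pos for m in self.mutations]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.allele}: duplicate mutation positions")

    def inverse(self) -> "VariantDef":
        return VariantDef(self.allele, frozenset(m.inverse() for m in self.mutations))


@dataclass(frozen=True)
class StabilityCall:
    ddG_kcal_mol: float
    label: str  # limited_effect | potentially_destabilising


def builtin_variants() -> dict[str, VariantDef]:
    """The built-in CYP2D6 allele table, keyed by star name."""

    def _v(allele: str, *tokens: str) -> VariantDef:
        return VariantDef(allele, frozenset(Mutation.parse(t) for t in tokens))

    variants = [
        _v("*1"),
        _v("*14A", "P34S", "G169R", "R296C", "S486T"),
        _v("*51", "R296C", "E334A", "S486T"),
        _v("*110", "G445R"),
        _v("*122", "V370I"),
    ]
    return {v.allele: v for v in variants}


def apply_mutations(seq: str, offset: int, v: VariantDef) -> str:
    """Apply a variant's missense mutations to a one-letter sequence.

    ``offset`` is the author residue number of ``seq[0]``. Every mutation's
    wild-type residue is checked against the sequence before any change is
    made, guarding against numbering drift.
    """
    chars = list(seq)
    for m in sorted(v.mutations, key=lambda m: m.pos):
        idx = m.pos - offset
        if not (0 <= idx < len(chars)):
            raise MutationError(
                f"{v.allele} {m}: position {m.pos} outside sequence "
                f"(residues {offset}..{offset + len(chars) - 1})"
            )
        if chars[idx] != m.wt:
            raise MutationError(
                f"{v.allele} {m}: expected {m.wt} at position {m.pos}, "
                f"found {chars[idx]}"
            )
    for m in v.mutations:
        chars[m.pos - offset] = m.mut
    return "".join(chars)


def classify_stability(ddG_kcal_mol: float) -> StabilityCall:
    """Classify a mutation's predicted ΔΔG against the 1 kcal/mol rule.

    Strictly below 1 kcal/mol → ``limited_effect``; at or above the
    threshold → ``potentially_destabilising``.
    """
    ddG = float(ddG_kcal_mol)
    if not math.isfinite(ddG):
        raise ValueError(f"ΔΔG must be finite, got {ddG_kcal_mol!r}")
    label = (
        "limited_effect" if ddG < DDG_THRESHOLD_KCAL_MOL else "potentially_destabilising"
    )
    return StabilityCall(ddG_kcal_mol=ddG, label=label)


def mutation_site_distances(
    s: Structure,
    chain: str,
    v: VariantDef,
    fe_index: int,
    cutoff_nm: float = PROXIMITY_CUTOFF_NM,
) -> pd.DataFrame:
    """Minimum distance (nm) from each mutated residue to the heme iron.

    One row per mutation with columns ``pos``, ``min_distance_nm`` (minimum
    over all the residue's atoms) and ``annotation`` ("proximal" below the
    cut-off, else "distal"). Distal mutation sites are unlikely to reshape
    the substrate-binding architecture directly.
    """
    fe_xyz = np.asarray(s.atoms[fe_index].xyz, dtype=float)
    rows = []
    for m in sorted(v.mutations, key=lambda m: m.pos):
        res_xyz = np.array(
            [
                a.xyz
                for a in s.atoms
                if a.chain_id == chain and a.res_seq == m.pos and not a.hetero
            ],
            dtype=float,
        )
        if res_xyz.size == 0:
            raise StructureError(
                f"{v.allele} {m}: residue {m.pos} not found in chain {chain!r}"
            )
        d_nm = float(np.min(np.linalg.norm(res_xyz - fe_xyz, axis=1)) / 10.0)
        rows.append(
            {
                "pos": m.pos,
                "mutation": str(m),
                "min_distance_nm": d_nm,
                "annotation": "proximal" if d_nm < cutoff_nm else "distal",
            }
        )
    return pd.DataFrame(rows, columns=["pos", "mutation", "min_distance_nm", "annotation"])


def read_variant_table(path: str | Path) -> dict[str, VariantDef]:
    """Read a variant table: TSV with columns ``allele`` and ``mutations``
    (semicolon-separated tokens like ``G445R``; empty for the reference)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    variants = {}
    for _, row in df.iterrows():
        tokens = [t for t in row["mutations"].split(";") if t.strip()]
        variants[row["allele"]] = VariantDef(
            row["allele"], frozenset(Mutation.parse(t) for t in tokens)
        )
    return variants


def read_ddg_table(path: str | Path) -> pd.DataFrame:
    """Read ΔΔG annotations (TSV: allele, ddG_kcal_mol) and classify each."""
    df = pd.read_csv(path, sep="\t")
    df["label"] = [classify_stability(x).label for x in df["ddG_kcal_mol"]]
    return df
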