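"""Inter-subunit Cα-Cα distances from coordinate files.

Engineered disulfide pairs that crosslink the ankyrin-repeat "finger 3" tip
of one channel subunit to the three-stranded β-sheet of the *adjacent*
subunit are designed from the closed- and open-state structures of the
tetramer: a candidate cysteine pair is judged by the distance between the
two residues' Cα atoms in each state.  This module measures those distances
from mmCIF (preferred) or legacy PDB files via gemmi.

Because which of the two cyclic neighbours the interface partner sits on is
a labelling convention, :func:`pair_report` measures the pair across every
cyclic chain pairing (i -> i+1 in both directions) and reports the minimal
one per direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "ResiduePairDistance",
    "ResidueLookupError",
    "ca_position",
    "ca_distance",
    "pair_report",
]


class ResidueLookupError(KeyError):
    """Residue or its Cα atom missing from a structure."""


@dataclass(frozen=True)
class ResiduePairDistance:
    """Cα-Cα distance of one residue pair in one structure."""

    structure_id: str
    chain_a: str
    resid_a: int
    chain_b: str
    resid_b: int
    distance: float  # Å
    state_label: str = ""
    resolved: bool = True


def _load(structure) -> gemmi.Structure:
    if isinstance(structure, gemmi.Structure):
        return structure
    st = gemmi.read_structure(str(structure))
    st.setup_entities()
    return st


def ca_position(st: gemmi.Structure, chain: str, resid: int) -> np.ndarray:
    """Cα coordinates (Å) of a residue; first model, first alt-loc."""
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ResidueLookupError(f"chain {chain} not found in {st.name}")
    for res in ch:
        if res.seqid.num == resid:
            ca = res.find_atom("CA", "*")
            if ca is None:
                raise ResidueLookupError(f"no CA atom in {chain}:{resid}")
            return np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    raise ResidueLookupError(f"residue {chain}:{resid} not found")


def ca_distance(structure, pair_a, pair_b) -> float:
    """Euclidean Cα-Cα distance in Å between (chain, resid) pairs.

    Symmetric in the pair order.  Raises :class:`ResidueLookupError` naming
    the offending chain:resid if either residue or its Cα is absent.
    """
    st = _load(structure)
    a = ca_position(st, *pair_a)
    b = ca_position(st, *pair_b)
    return float(np.linalg.norm(a - b))


def _protein_chains(st: gemmi.Structure) -> list[str]:
    model = st[0]
    return [ch.name for ch in model if any(r.find_atom("CA", "*") for r in ch)]


def pair_report(
    closed_file,
    open_file,
    pairs,
    chains: list[str] | None = None,
    all_pairings: bool = False,
) -> list[ResiduePairDistance]:
    """Distances of residue pairs across adjacent subunits, both states.

    ``pairs`` is an iterable of ``(resid_a, resid_b)`` residue numbers where
    the first residue lives on one subunit and the second on a cyclically
    adjacent one.  For each state and pair the distance is evaluated across
    all cyclic chain pairings in both directions (i -> i+1 and i -> i-1 in
    the tetramer's cyclic chain order) and the minimum is reported — the
    designed contact is by construction the shortest inter-subunit
    realisation of the pair.  Unresolvable pairs are flagged (``resolved
    False``, distance NaN), not dropped.  With ``all_pairings=True`` every
    resolvable cyclic pairing is returned instead of only the minimum.
    """
    out = []
    for label, path in (("closed", closed_file), ("open", open_file)):
        st = _load(path)
        names = chains if chains is not None else _protein_chains(st)
        sid = st.name or Path(str(path)).stem
        for ra, rb in pairs:
            best = None
            for k, ca in enumerate(names):
                for cb in (names[(k + 1) % len(names)], names[(k - 1) % len(names)]):
                    if cb == ca:
                        continue
                    try:
                        d = ca_distance(st, (ca, ra), (cb, rb))
                    except ResidueLookupError:
                        continue
                    if all_pairings:
                        out.append(
                            ResiduePairDistance(sid, ca, ra, cb, rb,
                                                round(d, 1), label)
                        )
                    if best is None or d < best[0]:
                        best = (d, ca, cb)
            if all_pairings:
                if best is None:
                    out.append(
                        ResiduePairDistance(sid, "?", ra, "?", rb, float("nan"),
                                            label, resolved=False)
                    )
                continue
            if best is None:
                out.append(
                    ResiduePairDistance(sid, "?", ra, "?", rb, float("nan"),
                                        label, resolved=False)
                )
            else:
                d, ca_name, cb_name = best
                out.append(
                    ResiduePairDistance(sid, ca_name, ra, cb_name, rb,
                                        round(d, 1), label)
                )
    return out
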