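"""Machine-readable structures (SMILES/SDF) with cis double-bond isomers.

Every species maps to one or more explicit structures: the glycerol
backbone (sn-2 stereocentre specified, *sn*-glycero-3-phosphate
configuration), the headgroup esterified to the *sn*-3 phosphate, and the
two chains attached with their declared linkage chemistry (ester, ether,
or vinyl ether).  Chain double bonds are placed according to a
:class:`DoubleBondPattern`; all placed bonds are emitted in cis (Z)
configuration, and patterns must keep consecutive double-bond starts at
least ``d`` carbons apart (default 2, which forbids cumulated dienes but
allows conjugation).

The canonical structure of a species uses the "sequential"
earliest-position pattern on both chains; :func:`all_structures` emits the
full cartesian product of legal sn-1 and sn-2 patterns.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from math import comb
from typing import Dict, List, Sequence, Tuple

from rdkit import Chem, RDLogger
from rdkit.Chem import rdMolDescriptors

from .components import Chain, Headgroup, Linkage, Species
from .enumerate import ChainRule, DEFAULT_RULE

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "DoubleBondPattern",
    "StructureRecord",
    "placements",
    "placements_count",
    "sequential_pattern",
    "to_structure",
    "canonical_structure",
    "all_structures",
    "write_smiles",
    "write_sdf",
]

#: Strictly increasing double-bond start carbons; bond k occupies (s_k, s_k+1).
DoubleBondPattern = Tuple[int, ...]


@dataclass(frozen=True)
class StructureRecord:
    """One generated structure: species name, bond patterns, SMILES, formula."""

    name: str
    sn1_pattern: DoubleBondPattern
    sn2_pattern: DoubleBondPattern
    smiles: str
    formula: str


def placements_count(c: int, u: int, linkage: Linkage, rule: ChainRule = DEFAULT_RULE) -> int:
    """Number of legal patterns: the stars-and-bars closed form.

    Equals ``C((c - s_min) - (d - 1)(u - 1), u)`` when that argument is
    >= u, else 0; exactly one (empty) pattern when u = 0.
    """
    if u == 0:
        return 1
    if linkage is Linkage.HYDROXYL:
        raise ValueError("hydroxyl positions carry no double bonds")
    s_min, d = rule.s_min(linkage), rule.d
    n = (c - s_min) - (d - 1) * (u - 1)
    return comb(n, u) if n >= u else 0


def placements(c: int, u: int, linkage: Linkage, rule: ChainRule = DEFAULT_RULE) -> List[DoubleBondPattern]:
    """All legal double-bond patterns, lexicographically ordered.

    The first element is the "sequential" earliest-position pattern.
    An infeasible (c, u) yields an empty list; u = 0 yields ``[()]``.
    """
    if u == 0:
        return [()]
    if linkage is Linkage.HYDROXYL:
        raise ValueError("hydroxyl positions carry no double bonds")
    s_min, d = rule.s_min(linkage), rule.d
    out: List[DoubleBondPattern] = []

    def rec(prefix: List[int], next_min: int) -> None:
        k = len(prefix)
        if k == u:
            out.append(tuple(prefix))
            return
        # bonds still to place after this one need d carbons each; the
        # bond itself occupies (s, s+1) so s <= c-1 for the last bond
        last_feasible = (c - 1) - d * (u - 1 - k)
        for s in range(next_min, last_feasible + 1):
            rec(prefix + [s], s + d)

    rec([], s_min)
    return out


def sequential_pattern(chain: Chain, rule: ChainRule = DEFAULT_RULE) -> DoubleBondPattern:
    """Earliest-position pattern for a chain (empty for lyso/saturated)."""
    if chain.is_lyso or chain.u == 0:
        return ()
    pats = placements(chain.c, chain.u, chain.linkage, rule)
    if not pats:
        raise ValueError(f"chain {chain.token()} admits no double-bond placement")
    return pats[0]


# ---------------------------------------------------------------------------
# SMILES assembly.
#
# The molecule is assembled as one SMILES string from authored fragments.
# RDKit numbers atoms in their order of appearance in the input string, so
# chain-carbon atom indices are tracked while the string is built and used
# afterwards to set cis stereo on exactly the declared double bonds.

_ATOM_TOKEN = re.compile(r"\[[^\]]+\]|[CNOP]")


def _atom_count(fragment: str) -> int:
    return len(_ATOM_TOKEN.findall(fragment))


_HEAD_FRAGMENTS: Dict[str, Tuple[str, str]] = {
    # id -> (phosphate hydroxyl atom, headgroup fragment on the sn-3 phosphate)
    "PA": ("O", "O"),
    "PPA": ("O", "OP(=O)(O)O"),
    "PC": ("[O-]", "OCC[N+](C)(C)C"),          # zwitterion, net neutral
    "PE": ("O", "OCCN"),
    "PS": ("O", "OCC(N)C(=O)O"),
    "PG": ("O", "OCC(O)CO"),
    "PGP": ("O", "OCC(O)COP(=O)(O)O"),
    "CDPDG": ("O", "OP(=O)(O)OCC1OC(N2C=CC(N)=NC2=O)C(O)C1O"),
}

# Inositol ring templates; the stereo variant is the intended 1D-myo
# configuration (opt-in: the paper-style 2D skeletal drawings carry no
# ring stereo, so the default output is stereo-free on the ring).
_INOSITOL_STEREO = ("[C@@H]1", "[C@H]", "[C@@H]", "[C@H]", "[C@H]", "[C@@H]1")
_INOSITOL_FLAT = ("C1", "C", "C", "C", "C", "C1")


def _inositol_fragment(positions: Sequence[int], stereo: bool) -> str:
    atoms = _INOSITOL_STEREO if stereo else _INOSITOL_FLAT
    frag = "O" + atoms[0]
    for ring_pos in range(2, 7):
        sub = "(OP(=O)(O)O)" if ring_pos in positions else "(O)"
        frag += atoms[ring_pos - 1] + sub
    return frag


def _head_fragment(h: Headgroup, inositol_stereo: bool) -> Tuple[str, str]:
    if h.is_pi_family:
        return "O", _inositol_fragment(h.phosphate_positions, inositol_stereo)
    return _HEAD_FRAGMENTS[h.id]


def _chain_fragment(chain: Chain, pattern: DoubleBondPattern, offset: int
                    ) -> Tuple[str, Dict[int, int]]:
    """SMILES for one chain plus {chain carbon position -> atom index}.

    ``offset`` is the index of the atom immediately before the fragment
    (the backbone ester/ether oxygen).
    """
    if chain.is_lyso:
        return "", {}
    starts = set(pattern)
    if chain.linkage is Linkage.ALKENYL:
        starts.add(1)  # the vinyl-ether bond at carbons 1-2
    parts: List[str] = []
    index: Dict[int, int] = {}
    cursor = offset
    for i in range(1, chain.c + 1):
        bond = "=" if (i - 1) in starts else ""
        if i == 1 and chain.linkage is Linkage.ACYL:
            parts.append("C(=O)")
            cursor += 1
            index[1] = cursor
            cursor += 1  # the carbonyl oxygen
        else:
            parts.append(bond + "C")
            cursor += 1
            index[i] = cursor
    return "".join(parts), index


def _assemble(s: Species, p1: DoubleBondPattern, p2: DoubleBondPattern,
              inositol_stereo: bool) -> Tuple[str, Dict[str, Dict[int, int]], Dict[str, int]]:
    """Build the input SMILES and the chain-atom / anchor-oxygen indices.

    Atom order in the assembled string: backbone C1 (index 0), the sn-1
    oxygen and chain, backbone C2, the sn-2 oxygen and chain, then the
    phosphate and headgroup (whose indices are not needed).
    """
    p_oh, head = _head_fragment(s.headgroup, inositol_stereo)
    o_idx: Dict[str, int] = {}
    chain_idx: Dict[str, Dict[int, int]] = {"sn1": {}, "sn2": {}}

    o1_pos = 1
    frag1, chain_idx["sn1"] = _chain_fragment(s.sn1, p1, o1_pos)
    o1 = "O" + frag1
    if not s.sn1.is_lyso:
        o_idx["sn1"] = o1_pos

    c2_pos = o1_pos + _atom_count(o1)   # backbone C2 follows the o1 branch
    o2_pos = c2_pos + 1
    frag2, chain_idx["sn2"] = _chain_fragment(s.sn2, p2, o2_pos)
    o2 = "O" + frag2
    if not s.sn2.is_lyso:
        o_idx["sn2"] = o2_pos

    smiles = f"C({o1})[C@@H]({o2})COP(=O)({p_oh}){head}"
    return smiles, chain_idx, o_idx


def _assign_cis(mol: Chem.Mol, chain: Chain, pattern: DoubleBondPattern,
                index: Dict[int, int], ester_o: int) -> None:
    """Set Z stereo on each declared chain double bond.

    Stereo reference atoms are the chain-continuation neighbours (the
    backbone oxygen for the vinyl-ether bond), so Z means cis along the
    chain.  A terminal double bond (=CH2) carries no stereo.
    """
    if chain.is_lyso:
        return
    starts = list(pattern)
    if chain.linkage is Linkage.ALKENYL:
        starts = [1] + starts
    for st in starts:
        a, b = index[st], index[st + 1]
        bond = mol.GetBondBetweenAtoms(a, b)
        anchor_a = index[st - 1] if st >= 2 else ester_o
        anchor_b = index.get(st + 2)
        if anchor_b is None:
            continue
        bond.SetStereoAtoms(anchor_a, anchor_b)
        bond.SetStereo(Chem.BondStereo.STEREOZ)


def _validate_pattern(chain: Chain, pattern: DoubleBondPattern, rule: ChainRule) -> None:
    if chain.is_lyso or chain.u == 0:
        if pattern:
            raise ValueError(f"chain {chain.token()} admits only the empty pattern")
        return
    if len(pattern) != chain.u:
        raise ValueError(
            f"pattern {pattern} has {len(pattern)} bonds but chain "
            f"{chain.token()} declares {chain.u}"
        )
    s_min, d = rule.s_min(chain.linkage), rule.d
    prev = None
    for st in pattern:
        if st < s_min or st + 1 > chain.c:
            raise ValueError(f"bond start {st} out of range for chain {chain.token()}")
        if prev is not None and st - prev < d:
            raise ValueError(f"bond starts {prev},{st} violate minimum spacing {d}")
        prev = st


def to_structure(s: Species, p1: DoubleBondPattern, p2: DoubleBondPattern,
                 rule: ChainRule = DEFAULT_RULE, inositol_stereo: bool = False) -> StructureRecord:
    """Build one explicit structure for a species and a pattern pair.

    The returned SMILES parses in RDKit and its derived molecular formula
    equals the species composition.
    """
    _validate_pattern(s.sn1, p1, rule)
    _validate_pattern(s.sn2, p2, rule)
    smi, chain_idx, o_idx = _assemble(s, p1, p2, inositol_stereo)
    mol = Chem.MolFromSmiles(smi)
    if mol is None:  # pragma: no cover - template bug guard
        raise RuntimeError(f"internal SMILES template failed for {s.name}: {smi}")
    _assign_cis(mol, s.sn1, p1, chain_idx["sn1"], o_idx.get("sn1", -1))
    _assign_cis(mol, s.sn2, p2, chain_idx["sn2"], o_idx.get("sn2", -1))
    out = Chem.MolToSmiles(mol)
    formula = rdMolDescriptors.CalcMolFormula(Chem.MolFromSmiles(out))
    return StructureRecord(
        name=s.name, sn1_pattern=tuple(p1), sn2_pattern=tuple(p2),
        smiles=out, formula=formula,
    )


def all_structures(s: Species, rule: ChainRule = DEFAULT_RULE,
                   inositol_stereo: bool = False) -> List[StructureRecord]:
    """Every positional isomer: cartesian product of sn-1/sn-2 patterns."""
    pats1 = [()] if s.sn1.is_lyso else placements(s.sn1.c, s.sn1.u, s.sn1.linkage, rule)
    pats2 = [()] if s.sn2.is_lyso else placements(s.sn2.c, s.sn2.u, s.sn2.linkage, rule)
    return [
        to_structure(s, p1, p2, rule, inositol_stereo)
        for p1, p2 in itertools.product(pats1, pats2)
    ]


def canonical_structure(s: Species, rule: ChainRule = DEFAULT_RULE,
                        inositol_stereo: bool = False) -> StructureRecord:
    """The single "sequential" (earliest-position) structure."""
    return to_structure(s, sequential_pattern(s.sn1, rule), sequential_pattern(s.sn2, rule),
                        rule, inositol_stereo)


def write_smiles(records: Sequence[StructureRecord], path: str) -> None:
    """One record per line: SMILES, tab, name."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.name}\n")


def write_sdf(records: Sequence[StructureRecord], path: str) -> None:
    """SDF (v2000) with name and bond-pattern fields."""
    writer = Chem.SDWriter(path)
    try:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles)
            mol.SetProp("_Name", r.name)
            mol.SetProp("name", r.name)
            mol.SetProp("sn1_double_bond_starts", ",".join(map(str, r.sn1_pattern)) or "-")
            mol.SetProp("sn2_double_bond_starts", ",".join(map(str, r.sn2_pattern)) or "-")
            writer.write(mol)
    finally:
        writer.close()
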