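"""Reaction-SMARTS template mining and application.

The central objects are metabolic reaction templates: ``substrate_pattern >>
product_pattern`` SMARTS rules mined from atom-mapped substrate->metabolite
records. Extraction finds the reaction center (atoms whose environment
changes), expands it by one shell of non-hydrogen neighbors, keeps
leaving-group / gained atoms as unmapped context, and renders a canonical
string so identical transformations deduplicate into a frequency-ordered
library. Applying a template to a new substrate enumerates all matching sites
and returns the sanitized candidate metabolites.

Atom notation in rendered templates follows the house style used throughout
the library: center atoms carry element, aromaticity, hydrogen count, formal
charge and a map index (e.g. ``[NH;+0:1]``), first-shell neighbors carry
element + aromaticity + map only (``[C:2]``, ``[c:3]``), and context atoms
(leaving groups, gained oxygens) are unmapped (``O=C-``, ``[O-]``).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .reaction_io import ReactionRecord


class NoChangeDetected(ValueError):
    """Raised when substrate and product have identical mapped environments."""


class TemplateExtractionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pattern representation
# ---------------------------------------------------------------------------

_AROMATIC_ELEMS = {"b", "c", "n", "o", "p", "s", "se", "as", "te"}
_ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}


@dataclass
class PatternAtom:
    symbol: str  # element symbol, capitalized ("C", "Cl")
    aromatic: bool
    hcount: Optional[int]  # None = unspecified
    charge: Optional[int]  # None = unspecified
    map: int  # 0 = unmapped
    role: str  # "center" | "neighbor" | "context"


@dataclass
class Pattern:
    atoms: list[PatternAtom]
    bonds: list[tuple[int, int, str]]  # (i, j, bond token "-","=","#",":")

    def neighbors(self) -> list[list[tuple[int, str]]]:
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atoms]
        for i, j, t in self.bonds:
            adj[i].append((j, t))
            adj[j].append((i, t))
        return adj


_ATOM_TOKEN_RE = re.compile(r"^\[(.*?)(?::(\d+))?\]$")
_ELEM_RE = re.compile(r"^(\*|[A-Z][a-z]?|as|se|te|[bcnops])")


def _parse_atom_token(token: str) -> PatternAtom:
    """Parse one SMARTS atom token (as returned by RDKit ``Atom.GetSmarts``)."""
    m = _ATOM_TOKEN_RE.match(token)
    if m is None:  # bare organic-subset atom: C, O, c, n, Cl ...
        body, mapno = token, 0
    else:
        body = m.group(1)
        mapno = int(m.group(2)) if m.group(2) else 0
    em = _ELEM_RE.match(body)
    if em is None:
        raise TemplateExtractionError(f"cannot parse atom token {token!r}")
    elem = em.group(1)
    aromatic = elem[0].islower()
    symbol = elem.capitalize() if aromatic else elem
    rest = body[em.end():]
    hcount: Optional[int] = None
    charge: Optional[int] = None
    for prim in re.split(r"[;&]", rest):
        if not prim:
            continue
        if prim[0] == "H":
            hcount = int(prim[1:]) if prim[1:] else 1
        elif prim[0] in "+-":
            if prim in ("+", "-"):
                charge = 1 if prim == "+" else -1
            elif prim == len(prim) * prim[0]:  # "++", "--"
                charge = len(prim) * (1 if prim[0] == "+" else -1)
            else:
                charge = int(prim)
        else:
            raise TemplateExtractionError(f"unsupported SMARTS primitive {prim!r} in {token!r}")
    if mapno > 0 and (hcount is not None or charge is not None):
        role = "center"
    elif mapno > 0:
        role = "neighbor"
    else:
        role = "context"
    return PatternAtom(symbol, aromatic, hcount, charge, mapno, role)


def _parse_pattern_side(smarts: str) -> Pattern:
    atoms: list[PatternAtom] = []
    bonds: list[tuple[int, int, str]] = []
    offset = 0
    for part in smarts.split("."):
        q = Chem.MolFromSmarts(part)
        if q is None:
            raise TemplateExtractionError(f"unparsable SMARTS pattern {part!r}")
        for a in q.GetAtoms():
            atoms.append(_parse_atom_token(a.GetSmarts()))
        for b in q.GetBonds():
            t = b.GetSmarts()
            if t in ("", "~"):
                i, j = b.GetBeginAtom(), b.GetEndAtom()
                t = ":" if (i.GetIsAromatic() and j.GetIsAromatic()) else "-"
            bonds.append((offset + b.GetBeginAtomIdx(), offset + b.GetEndAtomIdx(), t))
        offset += q.GetNumAtoms()
    return Pattern(atoms, bonds)


# ---------------------------------------------------------------------------
# Canonical rendering
# ---------------------------------------------------------------------------

def _charge_token(c: int) -> str:
    if c == 1:
        return "+"
    if c == -1:
        return "-"
    return f"{c:+d}"


def _atom_token(a: PatternAtom) -> str:
    sym = a.symbol.lower() if a.aromatic else a.symbol
    if a.role == "context":
        if (a.charge or 0) != 0:
            return f"[{sym}{_charge_token(a.charge)}]"
        return sym if a.symbol in _ORGANIC_SUBSET else f"[{sym}]"
    if a.role == "neighbor":
        return f"[{sym}:{a.map}]"
    # center
    h = a.hcount
    c = a.charge if a.charge is not None else 0
    if c == 0:
        if h is None:
            return f"[{sym};+0:{a.map}]"
        if h == 0:
            return f"[{sym};H0;+0:{a.map}]"
        return f"[{sym}H{'' if h == 1 else h};+0:{a.map}]"
    htok = f";H{h}" if h is not None else ""
    return f"[{sym}{_charge_token(c)}{htok}:{a.map}]"


def _atom_invariant(a: PatternAtom, use_map: bool) -> tuple:
    return (
        a.symbol,
        a.aromatic,
        -1 if a.hcount is None else a.hcount,
        99 if a.charge is None else a.charge,
        a.role,
        a.map if use_map else (a.map > 0),
    )


def _canonical_ranks(p: Pattern, use_map: bool = False) -> list[int]:
    """Deterministic atom ranks via Weisfeiler-Lehman refinement.

    Remaining ties after refinement are between (in practice) automorphic
    atoms; they are broken by singling out one member of the lowest tied
    class and re-refining, which keeps the output independent of input
    atom order for the small tree-like patterns templates produce.
    """
    n = len(p.atoms)
    adj = p.neighbors()
    inv = [(_atom_invariant(a, use_map),) for a in p.atoms]

    def refine(inv):
        for _ in range(n):
            codes = {v: k for k, v in enumerate(sorted(set(inv)))}
            cur = [codes[v] for v in inv]
            new = [
                (cur[i], tuple(sorted((t, cur[j]) for j, t in adj[i])))
                for i in range(n)
            ]
            codes2 = {v: k for k, v in enumerate(sorted(set(new)))}
            nxt = [(codes2[v],) for v in new]
            if nxt == [(codes[v],) for v in inv]:
                return [codes[v] for v in inv]
            inv = nxt
        return [dict((v, k) for k, v in enumerate(sorted(set(inv))))[v] for v in inv]

    ranks = refine(inv)
    mark = n
    while len(set(ranks)) < n:
        # lowest rank value held by more than one atom
        tied_val = min(v for v in ranks if ranks.count(v) > 1)
        pick = min(i for i in range(n) if ranks[i] == tied_val)
        inv = [(ranks[i], 1 if i == pick else 0) for i in range(n)]
        mark += 1
        ranks = refine([(v,) for v in inv])
    return ranks


def _render_component(p: Pattern, comp: list[int], ranks: list[int]) -> str:
    adj = p.neighbors()
    comp_set = set(comp)
    # root: prefer terminal atoms, then lowest rank
    root = min(comp, key=lambda i: (len([1 for j, _ in adj[i] if j in comp_set]), ranks[i]))
    visited: set[int] = set()
    ring_bonds: dict[tuple[int, int], int] = {}
    ring_counter = [0]

    # pre-pass to find ring-closure (back) edges via DFS
    parent: dict[int, Optional[int]] = {root: None}
    stack = [root]
    order: dict[int, int] = {}
    t = 0
    back_edges: set[frozenset[int]] = set()
    while stack:
        u = stack.pop()
        if u in order:
            continue
        order[u] = t
        t += 1
        for v, _ in sorted(adj[u], key=lambda x: ranks[x[0]], reverse=True):
            if v not in comp_set:
                continue
            if v not in order:
                parent[v] = u
                stack.append(v)
            elif parent.get(u) != v and frozenset((u, v)) not in back_edges:
                back_edges.add(frozenset((u, v)))

    ring_digit: dict[frozenset[int], int] = {}
    for e in back_edges:
        ring_counter[0] += 1
        ring_digit[e] = ring_counter[0]

    def bond_tok(u: int, v: int) -> str:
        for j, tk in adj[u]:
            if j == v:
                return tk
        raise KeyError

    def write(u: int, from_atom: Optional[int]) -> str:
        visited.add(u)
        s = _atom_token(p.atoms[u])
        # ring closure digits at this atom
        for e, d in ring_digit.items():
            if u in e:
                v = next(iter(e - {u}))
                tk = bond_tok(u, v)
                s += (tk if tk != "-" else "") + str(d)
        children = [
            v for v, _ in sorted(adj[u], key=lambda x: ranks[x[0]])
            if v in comp_set and v != from_atom and frozenset((u, v)) not in ring_digit and v not in visited
        ]
        parts = []
        for idx, v in enumerate(children):
            sub = bond_tok(u, v) + write(v, u)
            parts.append(sub if idx == len(children) - 1 else "(" + sub + ")")
        return s + "".join(parts)

    return write(root, None)


def _render_pattern(p: Pattern, ranks: list[int]) -> str:
    # connected components, ordered by min rank
    n = len(p.atoms)
    adj = p.neighbors()
    seen: set[int] = set()
    comps: list[list[int]] = []
    for i in range(n):
        if i in seen:
            continue
        comp = []
        stack = [i]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            comp.append(u)
            stack.extend(j for j, _ in adj[u])
        comps.append(comp)
    comps.sort(key=lambda c: min(ranks[i] for i in c))
    return ".".join(_render_component(p, c, ranks) for c in comps)


def _canonical_reaction_string(sub: Pattern, prod: Pattern) -> str:
    sub_ranks = _canonical_ranks(sub, use_map=False)
    mapped = sorted((i for i, a in enumerate(sub.atoms) if a.map > 0), key=lambda i: sub_ranks[i])
    renum = {sub.atoms[i].map: k + 1 for k, i in enumerate(mapped)}
    sub2 = Pattern(
        [PatternAtom(a.symbol, a.aromatic, a.hcount, a.charge, renum.get(a.map, 0), a.role) for a in sub.atoms],
        list(sub.bonds),
    )
    missing = [a.map for a in prod.atoms if a.map > 0 and a.map not in renum]
    if missing:
        raise TemplateExtractionError(f"product maps {missing} absent from substrate side")
    prod2 = Pattern(
        [PatternAtom(a.symbol, a.aromatic, a.hcount, a.charge, renum.get(a.map, 0), a.role) for a in prod.atoms],
        list(prod.bonds),
    )
    # substrate rendered with map-free ranks (renumbering invariance); product
    # ranks may use the renumbered maps, which are themselves canonical
    sub_str = _render_pattern(sub2, _canonical_ranks(sub2, use_map=False))
    prod_str = _render_pattern(prod2, _canonical_ranks(prod2, use_map=True))
    return f"{sub_str}>>{prod_str}"


def normalize_template_smarts(smarts: str) -> str:
    """Strip (typographic) whitespace and canonically re-render a template."""
    compact = "".join(smarts.split())
    sides = compact.split(">>")
    if len(sides) != 2:
        raise TemplateExtractionError(f"not a reaction SMARTS: {smarts!r}")
    return _canonical_reaction_string(_parse_pattern_side(sides[0]), _parse_pattern_side(sides[1]))


# ---------------------------------------------------------------------------
# Template / library types
# ---------------------------------------------------------------------------

@dataclass
class ReactionTemplate:
    template_id: str
    smarts: str
    count: int = 0
    example_record_ids: list[str] = field(default_factory=list)

    @cached_property
    def rxn(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None:
            raise TemplateExtractionError(f"unparsable reaction SMARTS {self.smarts!r}")
        return rxn

    @property
    def center_maps(self) -> list[int]:
        sub = _parse_pattern_side(self.smarts.split(">>")[0])
        return sorted(a.map for a in sub.atoms if a.role == "center")


@dataclass
class TemplateLibrary:
    templates: list[ReactionTemplate]
    min_count: int = 1

    def __iter__(self):
        return iter(self.templates)

    def __len__(self):
        return len(self.templates)

    def __getitem__(self, template_id: str) -> ReactionTemplate:
        for t in self.templates:
            if t.template_id == template_id:
                return t
        raise KeyError(template_id)

    @classmethod
    def from_smarts(cls, smarts_list: Sequence[str], ids: Optional[Sequence[str]] = None,
                    counts: Optional[Sequence[int]] = None) -> "TemplateLibrary":
        templates = []
        for i, s in enumerate(smarts_list):
            templates.append(
                ReactionTemplate(
                    template_id=ids[i] if ids else f"T{i + 1:03d}",
                    smarts=normalize_template_smarts(s),
                    count=counts[i] if counts else 1,
                )
            )
        return cls(templates=templates, min_count=0)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("template_id\tsmarts\tcount\n")
            for t in self.templates:
                fh.write(f"{t.template_id}\t{t.smarts}\t{t.count}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TemplateLibrary":
        templates = []
        with Path(path).open("r", encoding="utf-8") as fh:
            header = fh.readline()
            assert header.startswith("template_id")
            for line in fh:
                tid, smarts, count = line.rstrip("\n").split("\t")
                templates.append(ReactionTemplate(tid, smarts, int(count)))
        return cls(templates=templates, min_count=min((t.count for t in templates), default=1))


# ---------------------------------------------------------------------------
# Reaction-center detection
# ---------------------------------------------------------------------------

def _mapped_atoms(mol: Chem.Mol) -> dict[int, Chem.Atom]:
    return {a.GetAtomMapNum(): a for a in mol.GetAtoms() if a.GetAtomMapNum() > 0}


def _atom_env_signature(atom: Chem.Atom) -> tuple:
    bonds = sorted(
        (b.GetBondTypeAsDouble(), b.GetOtherAtom(atom).GetAtomMapNum())
        for b in atom.GetBonds()
    )
    return (
        atom.GetSymbol(),
        atom.GetIsAromatic(),
        atom.GetFormalCharge(),
        atom.GetTotalNumHs(),
        atom.GetDegree(),
        tuple(bonds),
    )


def extract_reaction_center(record: ReactionRecord) -> set[int]:
    """Map indices of atoms whose bonding environment changed.

    Compares element, aromaticity, formal charge, attached-hydrogen count,
    heavy-atom degree and the multiset of (bond order, neighbor map) incident
    bonds between the substrate atom and its product image. Bond cleavage and
    formation show up through the bond multiset (a lost mapped neighbor or a
    gained unmapped atom changes it).
    """
    sub = record.substrate_mol
    prods = record.product_mols
    if sub is None or not prods:
        raise TemplateExtractionError(f"record {record.record_id} is not parseable")
    sub_maps = _mapped_atoms(sub)
    prod_maps: dict[int, Chem.Atom] = {}
    for p in prods:
        prod_maps.update(_mapped_atoms(p))
    center = {
        m
        for m in sub_maps.keys() & prod_maps.keys()
        if _atom_env_signature(sub_maps[m]) != _atom_env_signature(prod_maps[m])
    }
    if not center:
        raise NoChangeDetected(f"record {record.record_id}: no mapped environment change")
    return center


# ---------------------------------------------------------------------------
# Template extraction
# ---------------------------------------------------------------------------

def _build_substrate_pattern(sub: Chem.Mol, center_maps: set[int], retained: set[int],
                             radius: int) -> tuple[Pattern, dict[int, int]]:
    """Returns (pattern, mol_idx -> pattern_idx)."""
    by_map = _mapped_atoms(sub)
    roles: dict[int, str] = {}
    center_idx = [by_map[m].GetIdx() for m in center_maps]
    for i in center_idx:
        roles[i] = "center"
    frontier = list(center_idx)
    for _ in range(radius):
        nxt = []
        for i in frontier:
            for nb in sub.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in roles or nb.GetAtomicNum() <= 1:
                    continue
                mapno = nb.GetAtomMapNum()
                roles[j] = "neighbor" if (mapno > 0 and mapno in retained) else "context"
                nxt.append(j)
        frontier = nxt
    _complete_multiple_bonds(sub, roles, retained)
    return _pattern_from_roles(sub, roles)


def _complete_multiple_bonds(mol: Chem.Mol, roles: dict[int, str], retained: set[int]) -> None:
    """Pull in atoms attached by double/triple bonds (carbonyl completion)."""
    changed = True
    while changed:
        changed = False
        for i in list(roles):
            for b in mol.GetAtomWithIdx(i).GetBonds():
                if b.GetBondTypeAsDouble() not in (2.0, 3.0):
                    continue
                j = b.GetOtherAtomIdx(i)
                if j in roles:
                    continue
                mapno = mol.GetAtomWithIdx(j).GetAtomMapNum()
                roles[j] = "neighbor" if (mapno > 0 and mapno in retained) else "context"
                changed = True


def _pattern_from_roles(mol: Chem.Mol, roles: dict[int, str]) -> tuple[Pattern, dict[int, int]]:
    idx_order = sorted(roles)
    pat_idx = {i: k for k, i in enumerate(idx_order)}
    atoms = []
    for i in idx_order:
        a = mol.GetAtomWithIdx(i)
        role = roles[i]
        atoms.append(
            PatternAtom(
                symbol=a.GetSymbol(),
                aromatic=a.GetIsAromatic(),
                hcount=a.GetTotalNumHs() if role == "center" else None,
                charge=a.GetFormalCharge() if role == "center" else (
                    a.GetFormalCharge() if role == "context" and a.GetFormalCharge() != 0 else None
                ),
                map=a.GetAtomMapNum() if role != "context" else 0,
                role=role,
            )
        )
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in roles and j in roles:
            order = b.GetBondTypeAsDouble()
            tok = {1.0: "-", 1.5: ":", 2.0: "=", 3.0: "#"}[order]
            bonds.append((pat_idx[i], pat_idx[j], tok))
    return Pattern(atoms, bonds), pat_idx


def _build_product_pattern(prods: list[Chem.Mol], sub_pattern_maps: dict[int, str],
                           center_maps: set[int]) -> Pattern:
    """``sub_pattern_maps``: map index -> role on the substrate side."""
    all_atoms: list[PatternAtom] = []
    all_bonds: list[tuple[int, int, str]] = []
    offset = 0
    for p in prods:
        roles: dict[int, str] = {}
        by_map = _mapped_atoms(p)
        for m, role in sub_pattern_maps.items():
            if m in by_map:
                roles[by_map[m].GetIdx()] = "center" if m in center_maps else "neighbor"
        # gained atoms adjacent to center images
        for m in center_maps:
            if m not in by_map:
                continue
            for nb in by_map[m].GetNeighbors():
                if nb.GetAtomMapNum() == 0 and nb.GetAtomicNum() > 1 and nb.GetIdx() not in roles:
                    roles[nb.GetIdx()] = "context"
        _complete_multiple_bonds(p, roles, set(sub_pattern_maps))
        if not roles:
            continue
        pat, _ = _pattern_from_roles(p, roles)
        for a in pat.atoms:
            all_atoms.append(a)
        for i, j, t in pat.bonds:
            all_bonds.append((offset + i, offset + j, t))
        offset = len(all_atoms)
    return Pattern(all_atoms, all_bonds)


def extract_template(record: ReactionRecord, radius: int = 1) -> ReactionTemplate:
    """Mine the reaction-SMARTS template of one mapped record.

    The pattern covers the reaction center in full atomic detail, mapped
    non-hydrogen neighbors within ``radius`` bonds in element+aromaticity
    detail, and leaving/gained atoms as unmapped context. Double/triple-bonded
    partners of included atoms are pulled in so carbonyl-type context survives
    truncation.
    """
    center = extract_reaction_center(record)
    sub = record.substrate_mol
    prods = record.product_mols
    retained: set[int] = set()
    for p in prods:
        retained.update(_mapped_atoms(p))

    sub_pat, _ = _build_substrate_pattern(sub, center, retained, radius)
    sub_roles_by_map = {a.map: a.role for a in sub_pat.atoms if a.map > 0}
    prod_pat = _build_product_pattern(prods, sub_roles_by_map, center)
    # a mapped product atom pulled in by double-bond completion can be missing
    # from the substrate side; add it there as a plain neighbor so maps balance
    prod_maps = {a.map for a in prod_pat.atoms if a.map > 0}
    missing = prod_maps - set(sub_roles_by_map)
    if missing:
        by_map = _mapped_atoms(sub)
        roles, _ = _rebuild_roles(sub, center, retained, radius)
        for m in missing:
            roles.setdefault(by_map[m].GetIdx(), "neighbor")
        sub_pat, _ = _pattern_from_roles(sub, roles)
        sub_roles_by_map = {a.map: a.role for a in sub_pat.atoms if a.map > 0}
        prod_pat = _build_product_pattern(prods, sub_roles_by_map, center)

    if not prod_pat.atoms:
        raise TemplateExtractionError(
            f"record {record.record_id}: empty product pattern"
        )
    smarts = _canonical_reaction_string(sub_pat, prod_pat)
    tmpl = ReactionTemplate(template_id="", smarts=smarts, count=1,
                            example_record_ids=[record.record_id])
    tmpl.rxn  # validate it parses as a reaction
    return tmpl


def _rebuild_roles(sub: Chem.Mol, center_maps: set[int], retained: set[int],
                   radius: int) -> tuple[dict[int, str], dict[int, int]]:
    by_map = _mapped_atoms(sub)
    roles: dict[int, str] = {}
    center_idx = [by_map[m].GetIdx() for m in center_maps]
    for i in center_idx:
        roles[i] = "center"
    frontier = list(center_idx)
    for _ in range(radius):
        nxt = []
        for i in frontier:
            for nb in sub.GetAtomWithIdx(i).GetNeighbors():
                j = nb.GetIdx()
                if j in roles or nb.GetAtomicNum() <= 1:
                    continue
                mapno = nb.GetAtomMapNum()
                roles[j] = "neighbor" if (mapno > 0 and mapno in retained) else "context"
                nxt.append(j)
        frontier = nxt
    _complete_multiple_bonds(sub, roles, retained)
    return roles, {}


def canonicalize_template(template: ReactionTemplate | str) -> str:
    """Deterministic canonical string of a template.

    Atom maps are renumbered by canonical ranks of the substrate pattern and
    primitives are rendered in fixed order, so templates differing only by map
    numbering or token order collapse to the same string.
    """
    smarts = template.smarts if isinstance(template, ReactionTemplate) else template
    return normalize_template_smarts(smarts)


# ---------------------------------------------------------------------------
# Library construction
# ---------------------------------------------------------------------------

def build_template_library(
    records: Sequence[ReactionRecord],
    radius: int = 1,
    min_count: int = 1,
) -> tuple[TemplateLibrary, list[tuple[str, str]]]:
    """Extract + canonicalize every record's template and count duplicates.

    Returns the frequency-ordered library and a report of extraction failures
    as (record_id, reason) pairs. Templates below ``min_count`` are dropped.
    """
    groups: dict[str, list[str]] = {}
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            tmpl = extract_template(rec, radius=radius)
        except (NoChangeDetected, TemplateExtractionError) as exc:
            failures.append((rec.record_id, str(exc)))
            continue
        groups.setdefault(tmpl.smarts, []).append(rec.record_id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    templates = [
        ReactionTemplate(
            template_id=f"T{i + 1:04d}",
            smarts=smarts,
            count=len(rids),
            example_record_ids=rids,
        )
        for i, (smarts, rids) in enumerate(ordered)
        if len(rids) >= min_count
    ]
    return TemplateLibrary(templates=templates, min_count=min_count), failures


# ---------------------------------------------------------------------------
# Template application / candidate enumeration
# ---------------------------------------------------------------------------

def strip_stereo_canonical(mol_or_smiles: Chem.Mol | str) -> str:
    mol = Chem.MolFromSmiles(mol_or_smiles) if isinstance(mol_or_smiles, str) else Chem.Mol(mol_or_smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {mol_or_smiles!r}")
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    Chem.RemoveStereochemistry(mol)
    return Chem.MolToSmiles(mol)


def apply_template(template: ReactionTemplate, substrate: Chem.Mol | str) -> list[str]:
    """All distinct sanitized products of running the template at every site.

    Symmetric sites collapse by canonical-SMILES deduplication; unsanitizable
    products are discarded; the result is sorted lexicographically. No match
    returns an empty list.
    """
    mol = Chem.MolFromSmiles(substrate) if isinstance(substrate, str) else substrate
    if mol is None:
        raise ValueError("invalid substrate")
    out: set[str] = set()
    for pset in template.rxn.RunReactants((mol,)):
        for p in pset:
            try:
                q = Chem.Mol(p)
                for a in q.GetAtoms():
                    a.SetAtomMapNum(0)
                Chem.SanitizeMol(q)
                out.add(Chem.MolToSmiles(q))
            except Exception:
                continue
    return sorted(out)


@dataclass
class Candidate:
    smiles: str
    generating_template_ids: list[str]
    label: str  # "positive" | "negative"


@dataclass
class CandidateSet:
    substrate_smiles: str
    candidates: list[Candidate]
    record_id: Optional[str] = None

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def positive_indices(self) -> list[int]:
        return [i for i, c in enumerate(self.candidates) if c.label == "positive"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "record_id": self.record_id,
                "substrate": self.substrate_smiles,
                "candidates": [
                    {"smiles": c.smiles, "templates": c.generating_template_ids, "label": c.label}
                    for c in self.candidates
                ],
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "CandidateSet":
        d = json.loads(line)
        return cls(
            substrate_smiles=d["substrate"],
            candidates=[Candidate(c["smiles"], c["templates"], c["label"]) for c in d["candidates"]],
            record_id=d.get("record_id"),
        )


def write_candidate_sets(sets: Iterable[CandidateSet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for cs in sets:
            fh.write(cs.to_json() + "\n")


def read_candidate_sets(path: str | Path) -> list[CandidateSet]:
    with Path(path).open("r", encoding="utf-8") as fh:
        return [CandidateSet.from_json(line) for line in fh if line.strip()]


def generate_candidates(
    substrate: Chem.Mol | str,
    library: TemplateLibrary,
    recorded_products: Optional[Sequence[str]] = None,
    max_candidates: int = 128,
    seed: int = 0,
    record_id: Optional[str] = None,
) -> CandidateSet:
    """Enumerate and label all template-generated candidate metabolites.

    Every library template is applied at every matching site; candidates
    identical to the substrate are removed; positives are the candidates whose
    stereo-stripped canonical SMILES matches a recorded product. When the set
    exceeds ``max_candidates`` all positives are kept and negatives are
    subsampled with a seeded PRNG.
    """
    if max_candidates < 1:
        raise ValueError("max_candidates must be >= 1")
    mol = Chem.MolFromSmiles(substrate) if isinstance(substrate, str) else substrate
    if mol is None:
        raise ValueError("invalid substrate")
    sub_canon = strip_stereo_canonical(mol)
    recorded = {strip_stereo_canonical(p) for p in (recorded_products or [])}

    by_smiles: dict[str, list[str]] = {}
    for tmpl in library:
        for smi in apply_template(tmpl, mol):
            key = strip_stereo_canonical(smi)
            if key == sub_canon:
                continue
            by_smiles.setdefault(key, []).append(tmpl.template_id)

    candidates = [
        Candidate(
            smiles=smi,
            generating_template_ids=sorted(set(tids)),
            label="positive" if smi in recorded else "negative",
        )
        for smi, tids in sorted(by_smiles.items())
    ]
    if len(candidates) > max_candidates:
        positives = [c for c in candidates if c.label == "positive"]
        negatives = [c for c in candidates if c.label == "negative"]
        n_neg = max(0, max_candidates - len(positives))
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(negatives), size=n_neg, replace=False)
        negatives = [negatives[i] for i in sorted(pick)]
        candidates = sorted(positives + negatives, key=lambda c: c.smiles)
    return CandidateSet(substrate_smiles=Chem.MolToSmiles(mol), candidates=candidates,
                        record_id=record_id)
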