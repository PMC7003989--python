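"""Synthetic atom-mapped metabolic-reaction corpora with planted ground truth.

Real curated metabolic-reaction collections are proprietary, so testing the
mining -> enumeration -> ranking pipeline needs a generator that emulates one:
scaffolds assembled from a fragment grammar that guarantees coverage of the
common metabolizable groups (amides, esters, tertiary amines, thioethers,
pyridine-type nitrogens, aromatic and aliphatic CH), and reactions planted by
applying one of a library of common biotransformation rules, chosen with
per-rule propensities that mimic the strongly skewed class frequencies of
real data (hydrolyses most common, heteroatom oxidations next).

Every generated record carries full atom maps plus a truth channel (which
rule was planted at which site), so template extraction, candidate labeling
and propensity recovery can all be checked against construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy import stats

from .featurize import encode_block, featurize_candidate_set
from .ranker import RankerModel, score_candidates
from .reaction_io import ReactionRecord
from .templates import (
    CandidateSet,
    TemplateLibrary,
    generate_candidates,
)

logger = logging.getLogger("metabopred")

#: Common human phase-I/II biotransformation rules used as the default planted
#: library, ordered from most to least frequent class. The tertiary-amine rule
#: is written as a proper N-oxidation ([O-] on the aminium nitrogen, in the
#: same notation as the pyridine rule): the oxide-less aminium variant would be
#: perceived as a radical cation and rejected by the free-radical filter.
COMMON_RULE_SMARTS: list[tuple[str, str]] = [
    ("amide_n_dealkylation", "O=C-[NH;+0:1]-[C:2]>>[C:2][NH2;+0:1]"),
    ("anilide_hydrolysis", "O=C-[NH;+0:1]-[c:2]>>[NH2;+0:1]-[c:2]"),
    ("ester_hydrolysis_alcohol", "O=C-[O;H0;+0:1]-[C:2]>>[C:2]-[OH;+0:1]"),
    ("ester_hydrolysis_acid", "[C]-[O;H0;+0:1]-[C:2]=[O:3]>>[O:3]=[C:2]-[OH;+0:1]"),
    ("tertiary_amine_n_oxidation",
     "[C:1]-[N;H0;+0:2](-[C:3])-[C:4]>>[O-]-[N+;H0:2](-[C:1])(-[C:3])-[C:4]"),
    ("diaryl_sulfoxidation", "[c:1]-[S;H0;+0:2]-[c:3]>>O=[S;H0;+0:2](-[c:1])-[c:3]"),
    ("aliphatic_hydroxylation", "[C:1]-[CH2;+0:2]-[C:3]>>O-[CH;+0:2](-[C:1])-[C:3]"),
    ("pyridine_n_oxidation", "[c:1]:[n;H0;+0:2]:[c:3]>>[O-]-[n+;H0:2](:[c:1]):[c:3]"),
    ("aromatic_hydroxylation", "[c:1]:[cH;+0:2]:[c:3]>>O-[c;H0;+0:2](:[c:1]):[c:3]"),
    ("dialkyl_sulfoxidation", "[C:1]-[S;H0;+0:2]-[C:3]>>O=[S;H0;+0:2](-[C:1])-[C:3]"),
]

#: geometric decay of per-rule planting weight down the frequency ordering
DEFAULT_PROPENSITY_RATIO = 0.7


def default_template_library() -> TemplateLibrary:
    ids = [name for name, _ in COMMON_RULE_SMARTS]
    smarts = [s for _, s in COMMON_RULE_SMARTS]
    return TemplateLibrary.from_smarts(smarts, ids=ids)


def default_propensities(n: int) -> np.ndarray:
    w = DEFAULT_PROPENSITY_RATIO ** np.arange(n)
    return w / w.sum()


@dataclass
class GeneratorConfig:
    n_records: int = 2000
    template_library: Optional[TemplateLibrary] = None
    propensities: Optional[Sequence[float]] = None  # aligned with library order
    scaffold_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        if self.propensities is not None:
            p = np.asarray(self.propensities, dtype=float)
            if not np.all(np.isfinite(p)) or np.any(p <= 0):
                raise ValueError("propensities must be positive and finite")


@dataclass
class SyntheticRecord(ReactionRecord):
    planted_template_id: str = ""
    planted_site: int = 0  # atom-map index of the (first) reaction-center atom


# ---------------------------------------------------------------------------
# Scaffold grammar
# ---------------------------------------------------------------------------

_ALKYL = ["CC", "CCC", "CCCC", "C(C)C", "CC(C)C", "CCCCC", "CCC(C)C"]
_ARYL = ["c1ccccc1", "c1ccc(C)cc1", "c1ccncc1", "c1ccc(CC)cc1"]
# bivalent linkers; left end bonds to the preceding fragment, right end
# continues. Hydrolyzable groups are drawn most often, mirroring the amide/
# ester-rich composition of curated metabolic corpora.
_LINKERS = ["C(=O)N", "NC(=O)", "C(=O)O", "OC(=O)", "S", "N(C)", "CC", "CCC"]
_LINKER_WEIGHTS = np.array([0.28, 0.14, 0.14, 0.08, 0.10, 0.10, 0.09, 0.07])

_DEFAULT_SCAFFOLD_PARAMS = {
    "n_heavy": (14, 36),
    "extra_linker_prob": 0.7,  # chance of a second linker segment
    "aryl_prob": 0.5,  # chance a terminal is aromatic rather than alkyl
}


def _draw_scaffold(rng: np.random.Generator, params: dict) -> str:
    def terminal() -> str:
        pool = _ARYL if rng.random() < params["aryl_prob"] else _ALKYL
        return pool[rng.integers(len(pool))]

    def linker() -> str:
        return _LINKERS[rng.choice(len(_LINKERS), p=_LINKER_WEIGHTS / _LINKER_WEIGHTS.sum())]

    parts = [terminal(), linker()]
    if rng.random() < params["extra_linker_prob"]:
        mid_pool = _ALKYL + ["Cc1ccc(C)cc1"]
        parts.append(mid_pool[rng.integers(len(mid_pool))])
        parts.append(linker())
    parts.append(terminal())
    return "".join(parts)


def generate_scaffolds(n: int, params: Optional[dict] = None, seed: int = 0,
                       library: Optional[TemplateLibrary] = None) -> list[Chem.Mol]:
    """n unique, valence-valid scaffolds, each matched by >= 1 library template.

    Deterministic per seed. Raises when the grammar cannot satisfy the
    parameters (e.g. an impossible heavy-atom range).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = {**_DEFAULT_SCAFFOLD_PARAMS, **(params or {})}
    lo, hi = params["n_heavy"]
    if lo > hi:
        raise ValueError("empty heavy-atom range")
    library = library or default_template_library()
    rng = np.random.default_rng(seed)
    out: list[Chem.Mol] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("scaffold grammar failed to produce enough unique scaffolds")
        smi = _draw_scaffold(rng, params)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        if not (lo <= mol.GetNumHeavyAtoms() <= hi):
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            continue
        if not _match_sites(mol, library):
            continue
        seen.add(canon)
        out.append(mol)
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _mapped_copy(mol: Chem.Mol) -> Chem.Mol:
    m = Chem.Mol(mol)
    for a in m.GetAtoms():
        a.SetAtomMapNum(a.GetIdx() + 1)
    return m


def _match_sites(mol: Chem.Mol, library: TemplateLibrary) -> dict[str, list[Chem.Mol]]:
    """template_id -> distinct mapped product molecules (one per site)."""
    mapped = _mapped_copy(mol)
    sites: dict[str, list[Chem.Mol]] = {}
    for tmpl in library:
        prods: dict[str, Chem.Mol] = {}
        for pset in tmpl.rxn.RunReactants((mapped,)):
            for p in pset:
                q = Chem.Mol(p)
                for a in q.GetAtoms():
                    if a.HasProp("react_atom_idx"):
                        a.SetAtomMapNum(int(a.GetProp("react_atom_idx")) + 1)
                    else:
                        a.SetAtomMapNum(0)
                try:
                    Chem.SanitizeMol(q)
                except Exception:
                    continue
                prods.setdefault(Chem.MolToSmiles(q), q)
        if prods:
            sites[tmpl.template_id] = [prods[k] for k in sorted(prods)]
    return sites


def _planted_site(product: Chem.Mol, tmpl) -> int:
    """Atom-map index (in the substrate numbering) of the template's first
    center atom at the planted site."""
    center = min(tmpl.center_maps) if tmpl.center_maps else None
    for a in product.GetAtoms():
        if center is not None and a.HasProp("old_mapno") and int(a.GetProp("old_mapno")) == center:
            if a.GetAtomMapNum() > 0:
                return a.GetAtomMapNum()
    # fallback: first mapped atom
    for a in product.GetAtoms():
        if a.GetAtomMapNum() > 0:
            return a.GetAtomMapNum()
    return 0


def template_match_weights(mol: Chem.Mol, library: TemplateLibrary,
                           propensities: np.ndarray) -> np.ndarray:
    """Conditional probability of planting each template on this scaffold.

    The planted template is drawn with probability proportional to its
    propensity among the templates that match; the site is then uniform
    within the chosen template, so site multiplicity does not inflate a
    template's planting mass.
    """
    sites = _match_sites(mol, library)
    ids = [t.template_id for t in library]
    w = np.zeros(len(ids))
    for i, tid in enumerate(ids):
        if tid in sites:
            w[i] = propensities[i]
    total = w.sum()
    return w / total if total > 0 else w


def generate_dataset(config: GeneratorConfig) -> list[SyntheticRecord]:
    """Plant one biotransformation per scaffold and emit mapped records.

    For each record a scaffold is drawn, all (template, site) matches are
    enumerated, one is sampled with probability proportional to the template
    propensity, and the mapped product is recorded together with the planted
    truth. Scaffolds are unique across records so downstream splits cannot
    leak substrates.
    """
    library = config.template_library or default_template_library()
    prop = (
        np.asarray(config.propensities, dtype=float)
        if config.propensities is not None
        else default_propensities(len(library))
    )
    if len(prop) != len(library):
        raise ValueError("propensities must align with the template library")
    prop = prop / prop.sum()
    ids = [t.template_id for t in library]

    rng = np.random.default_rng(config.seed)
    scaffolds = generate_scaffolds(config.n_records, config.scaffold_params,
                                   seed=config.seed + 1, library=library)
    records: list[SyntheticRecord] = []
    for i, mol in enumerate(scaffolds):
        sites = _match_sites(mol, library)
        if not sites:  # generate_scaffolds guarantees matches; belt and braces
            raise RuntimeError(f"scaffold {Chem.MolToSmiles(mol)} matches no template")
        matched = sorted(sites)
        w = np.asarray([prop[ids.index(tid)] for tid in matched])
        tid = matched[rng.choice(len(matched), p=w / w.sum())]
        product = sites[tid][rng.integers(len(sites[tid]))]
        mapped_sub = _mapped_copy(mol)
        rec = SyntheticRecord(
            record_id=f"syn{i:05d}",
            substrate_smiles=Chem.MolToSmiles(mapped_sub),
            product_smiles=[Chem.MolToSmiles(product)],
            source="synthetic",
            planted_template_id=tid,
            planted_site=_planted_site(product, library[tid]),
        )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Candidate sets + propensity recovery
# ---------------------------------------------------------------------------

def candidate_sets_from_records(records: Sequence[ReactionRecord], library: TemplateLibrary,
                                max_candidates: int = 128, seed: int = 0) -> list[CandidateSet]:
    """Labeled candidate sets for mapped records (maps stripped first)."""
    out = []
    for rec in records:
        sub = Chem.Mol(rec.substrate_mol)
        for a in sub.GetAtoms():
            a.SetAtomMapNum(0)
        out.append(
            generate_candidates(sub, library, recorded_products=rec.product_smiles,
                                max_candidates=max_candidates, seed=seed,
                                record_id=rec.record_id)
        )
    return out


def template_probability_mass(model, candidate_sets: Sequence[CandidateSet],
                              library: TemplateLibrary, radius: int = 2, n_bits: int = 1024,
                              encoder=None) -> dict[str, float]:
    """Mean model probability mass of the candidates each template generates.

    ``model`` may be a RankerModel, a scorer callable, or the string
    ``"oracle"`` (probability mass placed uniformly on the positives, an upper
    bound used for sanity checks).
    """
    mass: dict[str, list[float]] = {t.template_id: [] for t in library}
    for cs in candidate_sets:
        if cs.n_candidates == 0:
            continue
        if model == "oracle":
            probs = np.zeros(cs.n_candidates)
            pos = cs.positive_indices
            if pos:
                probs[pos] = 1.0 / len(pos)
        else:
            block = featurize_candidate_set(cs, radius=radius, n_bits=n_bits)
            if encoder is not None:
                block = encode_block(block, encoder)
            probs = score_candidates(model, block).probabilities
        for i, cand in enumerate(cs.candidates):
            for tid in cand.generating_template_ids:
                if tid in mass:
                    mass[tid].append(float(probs[i]))
    return {tid: float(np.mean(v)) for tid, v in mass.items() if v}


def recover_propensities(model, records: Sequence[ReactionRecord], library: TemplateLibrary,
                         propensities: Optional[Sequence[float]] = None,
                         radius: int = 2, n_bits: int = 1024, encoder=None,
                         candidate_sets: Optional[Sequence[CandidateSet]] = None,
                         max_candidates: int = 128) -> float:
    """Spearman rank correlation between planted propensities and the mean
    model probability mass per template.

    Templates that generated no candidate on these records are excluded (and
    logged). ``records`` should be disjoint from the training data.
    """
    if candidate_sets is None:
        candidate_sets = candidate_sets_from_records(records, library,
                                                     max_candidates=max_candidates)
    prop = (
        np.asarray(propensities, dtype=float)
        if propensities is not None
        else default_propensities(len(library))
    )
    mass = template_probability_mass(model, candidate_sets, library,
                                     radius=radius, n_bits=n_bits, encoder=encoder)
    ids = [t.template_id for t in library]
    used = [i for i, tid in enumerate(ids) if tid in mass]
    skipped = [tid for tid in ids if tid not in mass]
    if skipped:
        logger.info("templates with no generated candidates excluded: %s", skipped)
    if len(used) < 3:
        raise ValueError("too few templates with candidates to correlate")
    rho, _ = stats.spearmanr([prop[i] for i in used], [mass[ids[i]] for i in used])
    return float(rho)


def empirical_template_frequencies(records: Sequence[SyntheticRecord],
                                   library: TemplateLibrary) -> np.ndarray:
    counts = np.zeros(len(library))
    ids = [t.template_id for t in library]
    for rec in records:
        counts[ids.index(rec.planted_template_id)] += 1
    return counts


def write_truth_sidecar(records: Sequence[SyntheticRecord], path) -> None:
    import json
    from pathlib import Path

    data = [
        {"record_id": r.record_id, "template_id": r.planted_template_id, "site": r.planted_site}
        for r in records
    ]
    Path(path).write_text(json.dumps(data, indent=1), encoding="utf-8")
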