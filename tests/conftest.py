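"""Shared fixtures: printed golden rules, hand-mapped exemplar reactions,
a probe molecule panel, and small synthetic corpora."""

from __future__ import annotations

import pytest

from metabopred.reaction_io import record_from_reaction_smiles
from metabopred.synthetic import GeneratorConfig, default_template_library, generate_dataset

# The ten canonical biotransformation rules in their published typographic
# form (note the literal "> >" arrow and spaced bonds; row 6 even lacks a
# bond token). The whitespace-tolerant normalizer must cope with all of it.
PRINTED_RULES = [
    "O = C-[NH;+0:1]-[C:2]> > [C:2][NH2;+0:1]",
    "O = C-[NH;+0:1]-[c:2]> > [NH2;+0:1]-[c:2]",
    "O = C-[O;H0;+0:1]-[C:2]> > [C:2]-[OH;+0:1]",
    "[C]-[O;H0;+0:1]-[C:2] = [O:3]> > [O:3] = [C:2]-[OH;+0:1]",
    "[C:1]-[N;H0;+0:2](-[C:3])-[C:4]> > [C:1]-[N+;H0:2](-[C:3])(-[C:4])",
    "[c:1]-[S;H0;+0:2] [c:3]> > O = [S;H0;+0:2](-[c:1])-[c:3]",
    "[C:1]-[CH2;+0:2]-[C:3]> > O-[CH;+0:2](-[C:1])-[C:3]",
    "[c:1]:[n;H0;+0:2]:[c:3]> > [O-]-[n+;H0:2](:[c:1]):[c:3]",
    "[c:1]:[cH;+0:2]:[c:3]> > O-[c;H0;+0:2](:[c:1]):[c:3]",
    "[C:1]-[S;H0;+0:2]-[C:3]> > O = [S;H0;+0:2](-[C:1])-[C:3]",
]

# One hand-written atom-mapped exemplar reaction per rule, in the same order.
# Surviving substrate atoms carry maps; leaving-group atoms are unmapped on
# the substrate side and gained atoms are unmapped on the product side.
EXEMPLAR_REACTIONS = [
    "CC(=O)[NH:1][CH2:2][CH3:3]>>[NH2:1][CH2:2][CH3:3]",
    "CC(=O)[NH:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1"
    ">>[NH2:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1",
    "CC(=O)[O:1][CH2:2][CH3:3]>>[OH:1][CH2:2][CH3:3]",
    "[CH3:4][C:2](=[O:3])[O:1]CC>>[CH3:4][C:2](=[O:3])[OH:1]",
    "[CH3:1][CH2:2][N:3]([CH3:4])[CH3:5]>>[CH3:1][CH2:2][N+:3]([CH3:4])[CH3:5]",
    "[cH:1]1[cH:2][cH:3][cH:4][cH:5][c:6]1[S:7][c:8]1[cH:9][cH:10][cH:11][cH:12][cH:13]1"
    ">>O=[S:7]([c:6]1[cH:1][cH:2][cH:3][cH:4][cH:5]1)[c:8]1[cH:9][cH:10][cH:11][cH:12][cH:13]1",
    "[CH3:1][CH2:2][CH2:3][CH3:4]>>[CH3:1][CH:2](O)[CH2:3][CH3:4]",
    "[cH:1]1[cH:2][cH:3][n:4][cH:5][cH:6]1>>[O-][n+:4]1[cH:3][cH:2][cH:1][cH:6][cH:5]1",
    "[CH3:1][c:2]1[cH:3][cH:4][cH:5][cH:6][cH:7]1>>[CH3:1][c:2]1[cH:3][cH:4][c:5](O)[cH:6][cH:7]1",
    "[CH3:1][CH2:2][S:3][CH2:4][CH3:5]>>[CH3:1][CH2:2][S:3](=O)[CH2:4][CH3:5]",
]

# Probe molecules covering amides, anilides, esters, amines, thioethers,
# pyridines and plain hydrocarbons, used for behavioral template comparison.
PROBE_PANEL = [
    "CC(=O)NCCc1ccccc1",
    "CC(=O)Nc1ccc(C)cc1",
    "CCOC(C)=O",
    "CCCC(=O)OCC",
    "CCN(C)CC",
    "c1ccc(Sc2ccccc2)cc1",
    "CCSCC",
    "c1ccncc1",
    "Cc1ccccc1",
    "CCCCCC",
    "CC(C)CC(=O)NC",
    "CCC(=O)Nc1ccncc1",
    "COC(=O)c1ccccc1",
    "CCN(CC)CC",
    "CSc1ccccc1",
    "c1ccc2ncccc2c1",
    "CC(C)Cc1ccc(C)cc1C",
    "CCOC(=O)c1ccncc1",
    "CCC(=O)N(C)C",
    "OCCN(C)CCO",
]


@pytest.fixture(scope="session")
def printed_rules():
    return list(PRINTED_RULES)


@pytest.fixture(scope="session")
def exemplar_records():
    return [
        record_from_reaction_smiles(rxn, f"exemplar{i + 1}")
        for i, rxn in enumerate(EXEMPLAR_REACTIONS)
    ]


@pytest.fixture(scope="session")
def probe_panel():
    return list(PROBE_PANEL)


@pytest.fixture(scope="session")
def default_library():
    return default_template_library()


@pytest.fixture(scope="session")
def small_corpus():
    """80 synthetic mapped records with planted truth (fixed seed)."""
    return generate_dataset(GeneratorConfig(n_records=80, seed=5))
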