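"""Enumerated small-molecule fixtures with exact reference distributions.

Real training corpora (MOSES, ZINC-250K) are large downloads; every stage of
this package is instead exercised on closed-form enumerations whose target
distribution is known exactly, so distribution-recovery tests compare
against an analytic reference rather than another sample.

``enumerated_chains`` lists every unbranched heavy-atom chain over the
allowed elements up to a maximum length (O-O linkages are excluded by
default — unstable peroxide-type bonds), deduplicated by canonical SMILES
and weighted uniformly.  Over {C, O} with max length 3 this yields exactly
eight molecules: C, O, CC, CO, CCC, CCO, COC, OCO — a corpus whose logP
values split into a carbon-only and an oxygen-bearing mode, which doubles as
the conditional-generation fixture.

``ring_mix`` adds the small carbon rings to the chain set for
scaffold-bearing corpora.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from .metrics import property_panel
from .mol_graph import canonical_smiles

_ALLOWED_ELEMENTS = {"C", "N", "O"}


@dataclass(frozen=True)
class FixtureSpec:
    max_heavy_atoms: int = 3
    elements: tuple = ("C", "O")
    generator: str = "enumerated_chains"
    n_molecules: int = 256
    seed: int = 0
    forbid_o_o: bool = True

    def __post_init__(self):
        if self.max_heavy_atoms > 9:
            raise ValueError("fixtures are capped at 9 heavy atoms")
        if not set(self.elements) <= _ALLOWED_ELEMENTS:
            raise ValueError(f"elements must be within {_ALLOWED_ELEMENTS}")


@dataclass
class Fixture:
    molecules: list  # canonical SMILES, the enumerated support
    weights: np.ndarray  # exact reference probabilities, sums to 1
    properties: pd.DataFrame  # per-molecule smiles/qed/sas/logp/tpsa
    corpus: pd.DataFrame = field(repr=False, default=None)  # sampled training table

    def reference_distribution(self) -> dict:
        return dict(zip(self.molecules, self.weights))


def _enumerate_chains(spec: FixtureSpec):
    seen = {}
    for length in range(1, spec.max_heavy_atoms + 1):
        for combo in itertools.product(spec.elements, repeat=length):
            if spec.forbid_o_o and any(
                a == "O" and b == "O" for a, b in zip(combo, combo[1:])
            ):
                continue
            smiles = "".join(combo)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            seen.setdefault(canonical_smiles(smiles), None)
    return sorted(seen)


_RING_TEMPLATES = ["C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1"]


def _enumerate_ring_mix(spec: FixtureSpec):
    mols = set(_enumerate_chains(spec))
    for ring in _RING_TEMPLATES:
        if Chem.MolFromSmiles(ring).GetNumAtoms() <= spec.max_heavy_atoms:
            mols.add(canonical_smiles(ring))
    return sorted(mols)


_GENERATORS = {
    "enumerated_chains": _enumerate_chains,
    "ring_mix": _enumerate_ring_mix,
}


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Enumerate the support, attach uniform reference weights and RDKit
    property labels, and draw a seed-reproducible training corpus."""
    try:
        generator = _GENERATORS[spec.generator]
    except KeyError:
        raise ValueError(f"unknown fixture generator {spec.generator!r}")
    molecules = generator(spec)
    if not molecules:
        raise ValueError("fixture enumeration is empty")
    weights = np.full(len(molecules), 1.0 / len(molecules))
    records, _ = property_panel(molecules)
    properties = pd.DataFrame(records)
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(len(molecules), size=spec.n_molecules, p=weights)
    corpus = properties.iloc[draws].reset_index(drop=True)
    return Fixture(
        molecules=molecules, weights=weights, properties=properties, corpus=corpus
    )


def total_variation(observed, reference: dict) -> float:
    """TV distance between an observed sample of decode results (``None``
    allowed) and an exact reference distribution; any mass outside the
    reference support (including invalid decodes) counts fully against it."""
    N = len(observed)
    counts = {}
    for s in observed:
        counts[s] = counts.get(s, 0) + 1
    support = set(reference) | set(counts)
    return 0.5 * sum(
        abs(counts.get(s, 0) / N - reference.get(s, 0.0)) for s in support
    )
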