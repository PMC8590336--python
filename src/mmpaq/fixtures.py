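"""Synthetic combinatorial libraries with planted, exactly-known pair effects.

The generator enumerates scaffold x substituent libraries whose property is
additive: base value of the scaffold plus one planted contribution per
substituent, plus Gaussian noise.  Every substituent swap therefore has a
known transformation delta (the contribution difference), recorded in a
ground-truth table, so the whole MMP pipeline — fragmentation, pairing, rule
statistics — can be checked against exact expectations without any external
dataset.

Default library: two fused bicyclic heteroaromatic scaffolds, eight common
substituents (halogen / alkyl / polar, Hansch-pi-like contributions) at two
inequivalent sites.  Fused scaffolds keep every acyclic single bond a
substituent attachment, so the planted table is closed under MMP mining; the
substituents exercise fragment canonicalization edge cases (explicit
hydrogen, aromatic attachment, multi-atom groups).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

from mmpaq.molprep import MoleculeRecord


def _canon_fragment(smiles_with_site: str) -> str:
    mol = Chem.MolFromSmiles(smiles_with_site, sanitize=False)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


@dataclass
class Scaffold:
    """A substitution template: SMILES with [*:1], [*:2], ... site markers."""

    template: str
    base_value: float

    @property
    def n_sites(self) -> int:
        return len(re.findall(r"\[\*:\d+\]", self.template))


@dataclass
class Substituent:
    name: str
    smiles: str  # with one [*:1] attachment marker
    contribution: float


#: Hansch-pi-like lipophilicity contributions for the default substituents.
DEFAULT_SUBSTITUENTS = [
    Substituent("hydrogen", "[H][*:1]", 0.00),
    Substituent("fluoro", "F[*:1]", 0.14),
    Substituent("chloro", "Cl[*:1]", 0.71),
    Substituent("bromo", "Br[*:1]", 0.86),
    Substituent("methyl", "C[*:1]", 0.56),
    Substituent("hydroxy", "O[*:1]", -0.67),
    Substituent("amino", "N[*:1]", -1.23),
    Substituent("cyano", "N#C[*:1]", -0.57),
]

DEFAULT_SCAFFOLDS = [
    Scaffold("[*:1]c1ccc2nc([*:2])ccc2c1", 2.0),   # quinoline, 2,6-disubstituted
    Scaffold("[*:1]c1cc2cc([*:2])ccc2s1", 2.5),    # benzothiophene, 2,5-disubstituted
]

#: Larger scaffold panel for studies that need a scaffold-based QSAR split
#: (train/validation/test all get whole scaffold groups).  All fused bicyclics:
#: no acyclic ring-ring bond, so substituent attachments stay the only cuts.
EXTENDED_SCAFFOLDS = DEFAULT_SCAFFOLDS + [
    Scaffold("[*:1]c1cc2cc([*:2])ccc2o1", 2.3),    # benzofuran
    Scaffold("[*:1]c1cc2cc([*:2])ccc2[nH]1", 1.9), # indole
    Scaffold("[*:1]c1nc2cc([*:2])ccc2o1", 1.8),    # benzoxazole
    Scaffold("[*:1]c1nc2cc([*:2])ccc2s1", 2.1),    # benzothiazole
]


def extended_spec(noise_sd: float = 0.1, seed: int = 0,
                  n_molecules: int | None = None) -> "FixtureSpec":
    """Six-scaffold spec for QSAR-assisted studies (384 molecules at full size)."""
    return FixtureSpec(
        scaffolds=list(EXTENDED_SCAFFOLDS),
        noise_sd=noise_sd,
        seed=seed,
        n_molecules=n_molecules,
    )


@dataclass
class FixtureSpec:
    scaffolds: list[Scaffold] = field(default_factory=lambda: list(DEFAULT_SCAFFOLDS))
    substituents: list[Substituent] = field(
        default_factory=lambda: list(DEFAULT_SUBSTITUENTS)
    )
    noise_sd: float = 0.1
    label_threshold: float = 2.5
    seed: int = 0
    n_molecules: int | None = None  # None = full enumeration


def _assemble(scaffold: Scaffold, subs: tuple[Substituent, ...]) -> str:
    mol = Chem.MolFromSmiles(scaffold.template)
    if mol is None:
        raise ValueError(f"invalid scaffold template: {scaffold.template!r}")
    for site, sub in enumerate(subs, start=1):
        frag = Chem.MolFromSmiles(
            sub.smiles.replace("[*:1]", f"[*:{site}]"), sanitize=False
        )
        Chem.SanitizeMol(frag)
        mol = Chem.molzip(mol, frag)
    mol = Chem.RemoveHs(mol)
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def planted_transformations(spec: FixtureSpec) -> pd.DataFrame:
    """Ground-truth table: every substituent swap with its exact planted delta.

    Keys use the engine's canonical single-cut fragment strings, oriented so
    ``variable_from`` <= ``variable_to`` lexicographically (the pair
    orientation the miner emits); ``planted_delta`` is
    contribution(to) - contribution(from).
    """
    rows = []
    canon = {s.name: _canon_fragment(s.smiles) for s in spec.substituents}
    subs = sorted(spec.substituents, key=lambda s: canon[s.name])
    for i in range(len(subs)):
        for j in range(i + 1, len(subs)):
            a, b = subs[i], subs[j]
            rows.append(
                {
                    "variable_from": canon[a.name],
                    "variable_to": canon[b.name],
                    "name_from": a.name,
                    "name_to": b.name,
                    "planted_delta": b.contribution - a.contribution,
                }
            )
    return pd.DataFrame(rows)


def generate_library(
    spec: FixtureSpec | None = None, task: str = "regression"
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Enumerate the combinatorial library and its ground-truth table.

    Returns curated-style records (property = planted value + noise, or the
    thresholded 0/1 label in classification mode) and the planted
    transformation table.  Byte-identical output under a fixed seed.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    assignments = []
    for s_idx, scaffold in enumerate(spec.scaffolds):
        combos: list[tuple[Substituent, ...]] = [()]
        for _ in range(scaffold.n_sites):
            combos = [c + (sub,) for c in combos for sub in spec.substituents]
        for combo in combos:
            assignments.append((s_idx, scaffold, combo))
    if spec.n_molecules is not None and spec.n_molecules < len(assignments):
        idx = rng.choice(len(assignments), size=spec.n_molecules, replace=False)
        assignments = [assignments[i] for i in sorted(idx)]

    records, seen = [], {}
    for n, (s_idx, scaffold, combo) in enumerate(assignments):
        smiles = _assemble(scaffold, combo)
        if smiles in seen:
            raise ValueError(
                f"fixture collision: {smiles} from scaffold {s_idx} {combo}"
            )
        seen[smiles] = n
        value = scaffold.base_value + sum(s.contribution for s in combo)
        if spec.noise_sd > 0:
            value += float(rng.normal(0.0, spec.noise_sd))
        if task == "classification":
            prop: float = float(value >= spec.label_threshold)
        else:
            prop = float(value)
        records.append(
            MoleculeRecord(
                id=f"FX{n:05d}",
                smiles_canonical=smiles,
                property=prop,
                source="experimental",
            )
        )
    return records, planted_transformations(spec)
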