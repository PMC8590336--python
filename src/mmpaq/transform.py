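"""Apply compiled transformation rules to lead molecules and screen products.

A rule (variable_from -> variable_to) is applied by re-fragmenting the query
molecule: wherever variable_from occurs as a cuttable fragment with matching
attachment topology, it is replaced by variable_to (single site at a time —
the matched-pair definition is a change at one site).  Products are
standardized, deduplicated, and screened against structural alerts (SMARTS)
and simple property ranges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors

from mmpaq.molprep import MoleculeRecord, Rejection, standardize_molecule
from mmpaq.mmp import enumerate_fragmentations, reassemble, _relabel
from mmpaq.rules import TransformationRule


@dataclass
class TransformProduct:
    parent_id: str
    rule_key: tuple[str, str]
    product_smiles: str
    expected_effect: float | None
    filter_verdict: bool | None = None
    filter_reasons: list[str] = field(default_factory=list)


#: Small default structural-alert set (widely published reactive/promiscuity
#: motifs); users supply their own SMARTS file for serious screening.
DEFAULT_ALERTS = {
    "aldehyde": "[CX3H1](=O)[#6]",
    "acyl_halide": "[CX3](=O)[F,Cl,Br,I]",
    "michael_acceptor": "[CX3]=[CX3][CX3]=[OX1]",
    "nitro": "[N+](=O)[O-]",
    "azo": "N=N",
    "isocyanate": "N=C=O",
    "epoxide_aziridine": "[OX2r3,NX3r3]",
    "alkyl_halide": "[CX4][Cl,Br,I]",
    "thiol": "[SX2H]",
    "hydrazine": "[NX3][NX3]",
}

#: Lipinski-like default property ranges for the product screen.
DEFAULT_PROPERTY_RANGES = {
    "mw": (0.0, 500.0),
    "logp": (-5.0, 5.0),
    "hbd": (0, 5),
    "hba": (0, 10),
    "rotatable_bonds": (0, 10),
}


def _number_of_attachments(fragment_smiles: str) -> int:
    mol = Chem.MolFromSmiles(fragment_smiles, sanitize=False)
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def apply_rule(
    molecule: MoleculeRecord | str,
    rule: TransformationRule,
    max_heavy_variable: int = 13,
    min_ratio_context_to_variable: float = 0.0,
) -> list[TransformProduct]:
    """All single-site products of applying one rule to one molecule.

    Each fragmentation of the molecule whose variable part equals the rule's
    ``variable_from`` (up to attachment renumbering) is rebuilt with
    ``variable_to``; the same renumbering is applied to the replacement so
    the attachment correspondence is preserved.  Invalid or non-standardizable
    products are discarded; duplicates collapsed.
    """
    if isinstance(molecule, str):
        molecule = MoleculeRecord(id="query", smiles_canonical=molecule)
    v_from = Chem.MolFromSmiles(rule.variable_from, sanitize=False)
    v_to = Chem.MolFromSmiles(rule.variable_to, sanitize=False)
    if v_from is None or v_to is None:
        raise ValueError("malformed rule fragment strings")
    k = _number_of_attachments(rule.variable_from)
    if k == 0 or k != _number_of_attachments(rule.variable_to):
        raise ValueError("rule fragments must share attachment-point count")

    frags = enumerate_fragmentations(
        molecule,
        max_cuts=k,
        max_heavy_variable=max_heavy_variable,
        min_ratio_context_to_variable=min_ratio_context_to_variable,
        hydrogen_mode=True,
    )
    effect = rule.mean_delta if rule.task == "regression" else rule.toxicity_change
    labels = list(range(1, k + 1))
    products: dict[str, TransformProduct] = {}
    for frag in frags:
        if frag.n_cuts != k:
            continue
        for perm in itertools.permutations(labels):
            mapping = dict(zip(labels, perm))
            if _relabel(frag.variable_fragment, mapping) != rule.variable_from:
                continue
            inverse = {v: key for key, v in mapping.items()}
            replacement = _relabel(rule.variable_to, inverse)
            try:
                product = reassemble(frag.context_key, replacement)
            except Exception:
                continue
            std = standardize_molecule(product)
            if isinstance(std, Rejection):
                continue
            smi = std.smiles_canonical
            if smi != molecule.smiles_canonical and smi not in products:
                products[smi] = TransformProduct(
                    parent_id=molecule.id,
                    rule_key=(rule.variable_from, rule.variable_to),
                    product_smiles=smi,
                    expected_effect=effect,
                )
            break
    return [products[s] for s in sorted(products)]


def load_alerts(source: dict[str, str] | str | None = None) -> dict[str, Chem.Mol]:
    """Compile an alert set; a string is a path to 'name<TAB or space>SMARTS' lines."""
    if source is None:
        raw = dict(DEFAULT_ALERTS)
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raw = {}
        with open(source) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, smarts = line.split(None, 1)
                raw[name] = smarts.strip()
    compiled = {}
    for name, smarts in raw.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"unparseable alert SMARTS for {name!r}: {smarts!r}")
        compiled[name] = patt
    return compiled


def screen_products(
    products: list[TransformProduct],
    alert_set: dict[str, Chem.Mol] | None = None,
    property_ranges: dict[str, tuple[float, float]] | None = None,
) -> list[TransformProduct]:
    """Annotate each product with a pass/fail verdict and reasons.

    Property ranges cover molecular weight, a computed lipophilicity proxy
    (Crippen logP), H-bond donors/acceptors and rotatable bonds; alerts are
    substructure SMARTS.  An empty alert set with unbounded ranges passes
    everything.
    """
    alerts = alert_set if alert_set is not None else {}
    ranges = property_ranges if property_ranges is not None else {}
    getters = {
        "mw": Descriptors.MolWt,
        "logp": Descriptors.MolLogP,
        "hbd": Descriptors.NumHDonors,
        "hba": Descriptors.NumHAcceptors,
        "rotatable_bonds": Descriptors.NumRotatableBonds,
    }
    for product in products:
        mol = Chem.MolFromSmiles(product.product_smiles)
        reasons = []
        for name, patt in alerts.items():
            if mol.HasSubstructMatch(patt):
                reasons.append(f"alert:{name}")
        for prop, (lo, hi) in ranges.items():
            value = getters[prop](mol)
            if not lo <= value <= hi:
                reasons.append(f"range:{prop}={value:.2f}")
        product.filter_reasons = reasons
        product.filter_verdict = not reasons
    return products
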