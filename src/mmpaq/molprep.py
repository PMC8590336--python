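"""Structure curation: standardization, deduplication and scaffold computation.

Raw structure tables (SMILES columns or SD files) are turned into a consistent,
deduplicated set of :class:`MoleculeRecord` objects suitable for both QSAR
modeling and matched-molecular-pair mining.  The standardization cascade is:

1. parse check (unparseable input rejected),
2. dummy-atom / broken-bond rejection,
3. largest-organic-fragment selection (salt and mixture removal),
4. charge neutralization by a fixed rule list (quaternary nitrogens kept),
5. functional-group normalization and tautomer canonicalization,
6. uncommon-element and chirality flagging,
7. canonical SMILES generation.

Stereochemistry is preserved in records but ignored later when MMP context
keys are formed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Elements considered common in drug-like chemistry; anything else is flagged.
COMMON_ELEMENTS = frozenset("C H N O S P F Cl Br I B".split())

#: Sentinel scaffold string for acyclic molecules.
EMPTY_SCAFFOLD = ""

_NORMALIZER = rdMolStandardize.Normalizer()
_TAUTOMER_PARAMS = rdMolStandardize.CleanupParameters()
# stereo is preserved in records (only MMP context keys ignore it later)
_TAUTOMER_PARAMS.tautomerRemoveSp3Stereo = False
_TAUTOMER_PARAMS.tautomerRemoveBondStereo = False
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator(_TAUTOMER_PARAMS)


@dataclass(frozen=True)
class MoleculeRecord:
    """One curated compound.

    ``property`` is a real value in regression mode, a {0, 1} label in
    classification mode, or ``None`` for unlabeled inputs awaiting prediction.
    ``source`` distinguishes experimental measurements from accepted model
    predictions after applicability-domain filtering.
    """

    id: str
    smiles_canonical: str
    property: float | None = None
    source: str = "experimental"
    flags: frozenset[str] = frozenset()


@dataclass
class Rejection:
    """A structure that failed standardization, with a machine-readable reason."""

    raw: str
    reason: str


@dataclass
class CurationReport:
    n_input: int = 0
    n_rejected_parse: int = 0
    n_rejected_fragmented: int = 0
    n_desalted: int = 0
    n_neutralized: int = 0
    n_duplicates_merged: int = 0
    rejects: list[Rejection] = field(default_factory=list)


def _neutralize(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Neutralize charged atoms by hydrogen adjustment.

    Covers the classic rule list (carboxylate->acid, alkoxide->alcohol,
    thiolate->thiol, protonated amine->amine, etc.).  Quaternary nitrogens
    (no attached H to remove, four heavy neighbors) are deliberately kept
    charged: the permanent cation is chemically meaningful, e.g. for hERG
    liability.  Charges balanced by an adjacent opposite charge (ylides,
    nitro groups) are also left alone.
    """
    pattern = Chem.MolFromSmarts("[+1!h0!$([*]~[-1,-2,-3,-4]),-1!$([*]~[+1,+2,+3,+4])]")
    matches = [m[0] for m in mol.GetSubstructMatches(pattern)]
    if not matches:
        return mol, False
    mol = Chem.RWMol(mol)
    changed = False
    for idx in matches:
        atom = mol.GetAtomWithIdx(idx)
        charge = atom.GetFormalCharge()
        h_count = atom.GetTotalNumHs()
        if charge > 0 and h_count == 0:
            continue  # quaternary-type cation: no proton to remove
        atom.SetFormalCharge(0)
        atom.SetNumExplicitHs(max(0, h_count - charge))
        atom.UpdatePropertyCache()
        changed = True
    return mol.GetMol(), changed


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    """Pick the fragment with the most heavy atoms that contains carbon.

    Ties are broken by canonical SMILES order so the choice is deterministic.
    Returns None when no fragment contains carbon.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return None
    return max(organic, key=lambda f: (f.GetNumHeavyAtoms(), Chem.MolToSmiles(f)))


def standardize_molecule(raw_structure: str | Chem.Mol) -> MoleculeRecord | Rejection:
    """Standardize one raw structure; return a record or a tagged rejection.

    Accepts a SMILES string or an RDKit Mol (e.g. from an SD file).  The
    returned record carries curation flags: ``desalted``, ``neutralized``,
    ``tautomer_normalized``, ``uncommon_element``, ``has_chirality``.
    """
    if isinstance(raw_structure, Chem.Mol):
        mol = raw_structure
        raw = Chem.MolToSmiles(mol) if mol is not None else ""
    else:
        raw = raw_structure
        mol = Chem.MolFromSmiles(raw_structure)
    if mol is None:
        return Rejection(raw, "parse")
    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return Rejection(raw, "dummy_atom")
    # RDKit query/broken-bond artifacts surface as unspecified bonds
    if any(b.GetBondType() == Chem.BondType.UNSPECIFIED for b in mol.GetBonds()):
        return Rejection(raw, "broken_bond")

    flags: set[str] = set()
    n_frags = len(Chem.GetMolFrags(mol))
    if n_frags > 1:
        mol = _largest_organic_fragment(mol)
        if mol is None:
            return Rejection(raw, "inorganic")
        flags.add("desalted")
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return Rejection(raw, "parse")
    elif not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        return Rejection(raw, "inorganic")

    mol, neutralized = _neutralize(mol)
    if neutralized:
        flags.add("neutralized")

    before = Chem.MolToSmiles(mol)
    try:
        mol = _NORMALIZER.normalize(mol)
        mol = _TAUTOMERIZER.Canonicalize(mol)
    except Exception:
        return Rejection(raw, "standardization_failure")
    if Chem.MolToSmiles(mol) != before:
        flags.add("tautomer_normalized")

    elements = {a.GetSymbol() for a in mol.GetAtoms()}
    if not elements <= COMMON_ELEMENTS:
        flags.add("uncommon_element")
    if any(a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED for a in mol.GetAtoms()):
        flags.add("has_chirality")

    smiles = Chem.MolToSmiles(mol)
    return MoleculeRecord(id="", smiles_canonical=smiles, flags=frozenset(flags))


def deduplicate(
    records: list[MoleculeRecord],
    conflict_policy: str = "mean",
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Collapse records sharing a canonical structure.

    conflict_policy:
        ``mean``     — continuous values averaged;
        ``majority`` — labels resolved by majority vote (ties dropped);
        ``strict``   — any disagreement drops the structure entirely.

    Records are returned sorted by canonical SMILES so the result is
    independent of input order.
    """
    if conflict_policy not in {"mean", "majority", "strict"}:
        raise ValueError(f"unknown conflict policy: {conflict_policy!r}")
    report = CurationReport(n_input=len(records))
    groups: dict[str, list[MoleculeRecord]] = {}
    for rec in records:
        groups.setdefault(rec.smiles_canonical, []).append(rec)

    survivors: list[MoleculeRecord] = []
    for smiles in sorted(groups):
        group = sorted(groups[smiles], key=lambda r: r.id)
        report.n_duplicates_merged += len(group) - 1
        values = [r.property for r in group if r.property is not None]
        flags = frozenset().union(*(r.flags for r in group))
        if not values:
            merged_value = None
        elif len(set(values)) == 1:
            merged_value = values[0]
        elif conflict_policy == "mean":
            merged_value = float(sum(values)) / len(values)
        elif conflict_policy == "majority":
            counts = Counter(values).most_common()
            if len(counts) > 1 and counts[0][1] == counts[1][1]:
                report.rejects.append(Rejection(smiles, "label_conflict"))
                logger.info("dropping %s: tied label vote", smiles)
                continue
            merged_value = counts[0][0]
        else:  # strict
            report.rejects.append(Rejection(smiles, "value_conflict"))
            logger.info("dropping %s: conflicting values under strict policy", smiles)
            continue
        survivors.append(
            MoleculeRecord(
                id=group[0].id,
                smiles_canonical=smiles,
                property=merged_value,
                source=group[0].source,
                flags=flags,
            )
        )
    return survivors, report


def compute_scaffold(record: MoleculeRecord | str, kind: str = "murcko") -> str:
    """Murcko scaffold or carbon skeleton of a curated structure.

    The carbon skeleton is the Murcko scaffold with every heavy atom replaced
    by carbon and all bonds reduced to single — hetero analogues of one ring
    framework collapse onto the same skeleton.  Acyclic molecules map to the
    empty-scaffold sentinel ``""``.
    """
    if kind not in {"murcko", "carbon_skeleton"}:
        raise ValueError(f"unknown scaffold kind: {kind!r}")
    smiles = record.smiles_canonical if isinstance(record, MoleculeRecord) else record
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable structure: {smiles!r}")
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    if kind == "carbon_skeleton":
        scaffold = MurckoScaffold.MakeScaffoldGeneric(scaffold)
    return Chem.MolToSmiles(scaffold)


def curate_table(
    frame: pd.DataFrame,
    structure_col: str = "smiles",
    property_col: str | None = None,
    id_col: str | None = None,
    source: str = "experimental",
    conflict_policy: str = "mean",
    reject_uncommon: bool = False,
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Curate a molecule table end to end: standardize every row, deduplicate.

    The report's counts partition the input exactly: survivors + parse
    rejections + fragment/standardization rejections + merges + policy drops.
    """
    records: list[MoleculeRecord] = []
    report = CurationReport(n_input=len(frame))
    for i, row in enumerate(frame.itertuples(index=False)):
        raw = getattr(row, structure_col)
        result = standardize_molecule(raw)
        if isinstance(result, Rejection):
            if result.reason == "parse":
                report.n_rejected_parse += 1
            else:
                report.n_rejected_fragmented += 1
            report.rejects.append(result)
            continue
        if reject_uncommon and "uncommon_element" in result.flags:
            report.n_rejected_fragmented += 1
            report.rejects.append(Rejection(raw, "uncommon_element"))
            continue
        if "desalted" in result.flags:
            report.n_desalted += 1
        if "neutralized" in result.flags:
            report.n_neutralized += 1
        mol_id = str(getattr(row, id_col)) if id_col else f"M{i:06d}"
        value = float(getattr(row, property_col)) if property_col else None
        records.append(
            MoleculeRecord(
                id=mol_id,
                smiles_canonical=result.smiles_canonical,
                property=value,
                source=source,
                flags=result.flags,
            )
        )
    survivors, dedup_report = deduplicate(records, conflict_policy)
    report.n_duplicates_merged = dedup_report.n_duplicates_merged
    report.rejects.extend(dedup_report.rejects)
    return survivors, report


def read_structures(path: str, structure_col: str = "smiles") -> pd.DataFrame:
    """Read a delimited table (CSV/TSV by extension) or an SD file."""
    if path.endswith((".sdf", ".sd")):
        rows = []
        for mol in Chem.SDMolSupplier(path, sanitize=True):
            if mol is None:
                rows.append({structure_col: "<unparseable SD record>"})
                continue
            row = {structure_col: Chem.MolToSmiles(mol)}
            row.update(mol.GetPropsAsDict())
            rows.append(row)
        return pd.DataFrame(rows)
    sep = "\t" if path.endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def records_to_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles_canonical for r in records],
            "property": [r.property for r in records],
            "source": [r.source for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )
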