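"""Matched-molecular-pair engine: fragment enumeration and inverted-index pairing.

Each molecule is fragmented by cutting 1-3 acyclic single bonds between heavy
atoms.  Every fragmentation splits the molecule into a *variable* part (one
connected fragment carrying all attachment points) and a *context* (the
constant remainder, possibly multi-part for 2-3 cuts).  Contexts are reduced
to canonical keys; an inverted index from context key to (molecule, variable)
postings then yields all matched pairs by grouping, without any pairwise
substructure search.

Attachment points are written as ``[*:n]`` dummies.  Context keys are
canonicalized structurally (stereo dropped, attachment numbers renumbered by
canonical atom rank) so that equivalent contexts from different molecules
collide in the index.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from rdkit import Chem

from mmpaq.molprep import MoleculeRecord

logger = logging.getLogger(__name__)

MAX_CUTS_LIMIT = 3

#: canonical SMILES of the explicit-hydrogen variable fragment
HYDROGEN_VARIABLE = "[H][*:1]"


@dataclass(frozen=True)
class Fragmentation:
    molecule_id: str
    n_cuts: int
    context_key: str
    variable_fragment: str
    n_heavy_variable: int
    n_heavy_context: int


@dataclass(frozen=True)
class MatchedPair:
    """Two molecules sharing a context, in canonical orientation.

    ``variable_a``/``variable_b`` use a joint canonical attachment numbering
    (the same permutation applied to both sides), with ``variable_a`` the
    lexicographically smaller string.  ``delta`` is property(B) - property(A).
    """

    id_a: str
    id_b: str
    context_key: str
    variable_a: str
    variable_b: str
    delta: float
    n_cuts: int
    source_a: str = "experimental"
    source_b: str = "experimental"


def _canon(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _strip_stereo(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    return mol


def _relabel(smiles: str, mapping: dict[int, int]) -> str:
    """Apply a permutation to the attachment map numbers of a fragment SMILES."""
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    Chem.SanitizeMol(mol)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            atom.SetAtomMapNum(mapping[atom.GetAtomMapNum()])
    return _canon(mol)


def _eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds between two heavy atoms — the cuttable bonds."""
    return [
        b.GetIdx()
        for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE
        and not b.IsInRing()
        and b.GetBeginAtom().GetAtomicNum() > 1
        and b.GetEndAtom().GetAtomicNum() > 1
    ]


def _canonicalize_parts(
    context_frags: list[Chem.Mol], variable: Chem.Mol, n_cuts: int
) -> tuple[str, str] | None:
    """Renumber attachments canonically; return (context_key, variable_smiles).

    Numbering is derived from the context alone: components are sorted by
    their unlabeled canonical SMILES, and within a component dummies take the
    order in which they appear in its canonical output.  The variable is then
    canonicalized over all *context-preserving* label permutations so that
    symmetric contexts give one representative.
    """
    comps = []
    for frag in context_frags:
        frag = Chem.Mol(frag)
        dummy_old = []
        for atom in frag.GetAtoms():
            if atom.GetAtomicNum() == 0:
                dummy_old.append(atom.GetIdx())
                atom.SetAtomMapNum(0)
        bare = Chem.MolToSmiles(frag)
        order = [int(x) for x in frag.GetProp("_smilesAtomOutputOrder")[1:-1].split(",") if x]
        dummies_in_order = [i for i in order if frag.GetAtomWithIdx(i).GetAtomicNum() == 0]
        comps.append((bare, frag, dummies_in_order))
    comps.sort(key=lambda c: c[0])

    # old label -> new label, walking sorted components
    relabel_map: dict[int, int] = {}
    next_label = 1
    labeled_comps = []
    for bare, frag, dummy_idxs in comps:
        for idx in dummy_idxs:
            atom = frag.GetAtomWithIdx(idx)
            old = atom.GetIntProp("_origLabel")
            relabel_map[old] = next_label
            atom.SetAtomMapNum(next_label)
            next_label += 1
        labeled_comps.append(Chem.MolToSmiles(frag))
    if len(relabel_map) != n_cuts:
        return None
    context_key = ".".join(sorted(labeled_comps))

    variable = Chem.Mol(variable)
    for atom in variable.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(relabel_map[atom.GetIntProp("_origLabel")])
    var_smiles = _canon(variable)

    if n_cuts > 1:
        labels = list(range(1, n_cuts + 1))
        best = var_smiles
        for perm in itertools.permutations(labels):
            mapping = dict(zip(labels, perm))
            if mapping == dict(zip(labels, labels)):
                continue
            permuted_ctx = ".".join(
                sorted(_relabel(c, mapping) for c in labeled_comps)
            )
            if permuted_ctx == context_key:
                cand = _relabel(var_smiles, mapping)
                if cand < best:
                    best = cand
        var_smiles = best
    return context_key, var_smiles


def _hydrogen_fragmentations(
    record: MoleculeRecord, mol: Chem.Mol
) -> list[Fragmentation]:
    """Single-cut fragmentations with an explicit hydrogen as the variable part."""
    out = {}
    n_heavy = mol.GetNumHeavyAtoms()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetTotalNumHs() == 0:
            continue
        rw = Chem.RWMol(mol)
        a = rw.GetAtomWithIdx(atom.GetIdx())
        if a.GetNumExplicitHs() > 0:
            a.SetNumExplicitHs(a.GetNumExplicitHs() - 1)
        else:
            a.SetNoImplicit(False)
        dummy = rw.AddAtom(Chem.Atom(0))
        rw.GetAtomWithIdx(dummy).SetAtomMapNum(0)
        rw.GetAtomWithIdx(dummy).SetIntProp("_origLabel", 1)
        rw.AddBond(atom.GetIdx(), dummy, Chem.BondType.SINGLE)
        ctx = rw.GetMol()
        try:
            Chem.SanitizeMol(ctx)
        except Exception:
            continue
        parts = _canonicalize_parts([ctx], _hydrogen_variable_mol(), 1)
        if parts is None:
            continue
        context_key, var_smiles = parts
        out[context_key] = Fragmentation(
            molecule_id=record.id,
            n_cuts=1,
            context_key=context_key,
            variable_fragment=var_smiles,
            n_heavy_variable=0,
            n_heavy_context=n_heavy,
        )
    return list(out.values())


def _hydrogen_variable_mol() -> Chem.Mol:
    var = Chem.MolFromSmiles("[H][*]", sanitize=False)
    Chem.SanitizeMol(var)
    for atom in var.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIntProp("_origLabel", 1)
    return var


def enumerate_fragmentations(
    record: MoleculeRecord,
    max_cuts: int = 3,
    max_heavy_variable: int = 13,
    min_ratio_context_to_variable: float = 1.0,
    hydrogen_mode: bool = True,
) -> list[Fragmentation]:
    """All valid cut-set decompositions of one molecule.

    Every subset of 1..max_cuts eligible bonds is tried; a cut set is valid
    when exactly one resulting fragment (the variable) carries all attachment
    points.  Constraints: the variable has at most ``max_heavy_variable``
    heavy atoms, and the context/variable heavy-atom ratio is at least
    ``min_ratio_context_to_variable``.  With ``hydrogen_mode`` each heavy atom
    bearing hydrogen additionally yields a single-cut fragmentation whose
    variable is an explicit hydrogen, enabling H->X transformations.

    Duplicate (context, variable) outcomes from different cut sets are
    emitted once.
    """
    if not 1 <= max_cuts <= MAX_CUTS_LIMIT:
        raise ValueError(f"max_cuts must be in [1, {MAX_CUTS_LIMIT}]")
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise ValueError(f"unparseable record structure: {record.smiles_canonical!r}")
    mol = _strip_stereo(mol)
    bonds = _eligible_bonds(mol)
    seen: dict[tuple[str, str], Fragmentation] = {}

    for k in range(1, max_cuts + 1):
        for cut_set in itertools.combinations(bonds, k):
            frag_mol = Chem.FragmentOnBonds(
                mol, list(cut_set), dummyLabels=[(i + 1, i + 1) for i in range(k)]
            )
            for atom in frag_mol.GetAtoms():
                if atom.GetAtomicNum() == 0:
                    atom.SetIntProp("_origLabel", atom.GetIsotope())
                    atom.SetIsotope(0)
            pieces = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
            for piece in pieces:
                try:
                    Chem.SanitizeMol(piece)
                except Exception:
                    pass
            labels_per_piece = [
                sorted(
                    a.GetIntProp("_origLabel")
                    for a in p.GetAtoms()
                    if a.GetAtomicNum() == 0
                )
                for p in pieces
            ]
            # role assignments: which piece is the variable part
            if k == 1:
                assignments = [(0, [1]), (1, [0])]
            else:
                full = [i for i, ls in enumerate(labels_per_piece) if len(ls) == k]
                if not full:
                    continue  # variable would be disconnected
                v = full[0]
                assignments = [(v, [i for i in range(len(pieces)) if i != v])]
            for var_i, ctx_is in assignments:
                variable = pieces[var_i]
                n_heavy_var = variable.GetNumHeavyAtoms()
                n_heavy_ctx = sum(pieces[i].GetNumHeavyAtoms() for i in ctx_is)
                if n_heavy_var > max_heavy_variable:
                    continue
                if n_heavy_ctx / max(n_heavy_var, 1) < min_ratio_context_to_variable:
                    continue
                parts = _canonicalize_parts([pieces[i] for i in ctx_is], variable, k)
                if parts is None:
                    continue
                context_key, var_smiles = parts
                key = (context_key, var_smiles)
                if key not in seen:
                    seen[key] = Fragmentation(
                        molecule_id=record.id,
                        n_cuts=k,
                        context_key=context_key,
                        variable_fragment=var_smiles,
                        n_heavy_variable=n_heavy_var,
                        n_heavy_context=n_heavy_ctx,
                    )

    frags = list(seen.values())
    if hydrogen_mode:
        existing = {(f.context_key, f.variable_fragment) for f in frags}
        for hf in _hydrogen_fragmentations(record, mol):
            if (hf.context_key, hf.variable_fragment) not in existing:
                frags.append(hf)
    return frags


def reassemble(context_key: str, variable_fragment: str) -> str:
    """Rejoin a context and a variable fragment into the parent canonical SMILES."""
    ctx = Chem.MolFromSmiles(context_key, sanitize=False)
    var = Chem.MolFromSmiles(variable_fragment, sanitize=False)
    combined = Chem.CombineMols(ctx, var)
    Chem.SanitizeMol(combined)
    merged = Chem.molzip(combined)
    merged = Chem.RemoveHs(merged)
    return Chem.MolToSmiles(merged)


def build_index(
    fragmentations: list[Fragmentation],
) -> dict[str, list[tuple[str, str, int]]]:
    """Inverted index: context key -> sorted postings of (molecule id, variable, n_cuts)."""
    index: dict[str, list[tuple[str, str, int]]] = {}
    for frag in fragmentations:
        index.setdefault(frag.context_key, []).append(
            (frag.molecule_id, frag.variable_fragment, frag.n_cuts)
        )
    for postings in index.values():
        postings.sort()
    return index


def canonical_transformation(
    variable_x: str, variable_y: str, n_cuts: int
) -> tuple[str, str, int]:
    """Canonical (from, to, sign) for a variable change under joint renumbering.

    Both fragments are relabeled with the same permutation (preserving the
    attachment correspondence given by the shared context); among all
    permutations and both directions the lexicographically smallest (from, to)
    is kept.  ``sign`` is +1 when the canonical direction is x->y, -1 when it
    is y->x.
    """
    if n_cuts == 1:
        if variable_x <= variable_y:
            return variable_x, variable_y, 1
        return variable_y, variable_x, -1
    labels = list(range(1, n_cuts + 1))
    best: tuple[str, str] | None = None
    best_sign = 1
    for perm in itertools.permutations(labels):
        mapping = dict(zip(labels, perm))
        x = _relabel(variable_x, mapping)
        y = _relabel(variable_y, mapping)
        for cand, sign in (((x, y), 1), ((y, x), -1)):
            if best is None or cand < best:
                best, best_sign = cand, sign
    return best[0], best[1], best_sign


def generate_mmps(
    index: dict[str, list[tuple[str, str, int]]],
    records: list[MoleculeRecord] | dict[str, MoleculeRecord],
) -> list[MatchedPair]:
    """All matched pairs from an inverted fragment index.

    For every context posting list, every unordered molecule pair with
    distinct variable fragments yields one pair; the same (molecule pair,
    transformation, context) arising from several cut sets is stored once.
    Pairs referencing a molecule without a property value are skipped.
    """
    by_id = (
        records
        if isinstance(records, dict)
        else {r.id: r for r in records}
    )
    pairs: dict[tuple, MatchedPair] = {}
    for context_key in sorted(index):
        postings = index[context_key]
        for (id_x, var_x, cuts_x), (id_y, var_y, cuts_y) in itertools.combinations(
            postings, 2
        ):
            if id_x == id_y or var_x == var_y:
                continue
            rec_x, rec_y = by_id.get(id_x), by_id.get(id_y)
            if rec_x is None or rec_y is None:
                continue
            if rec_x.property is None or rec_y.property is None:
                logger.info("skipping pair (%s, %s): missing property", id_x, id_y)
                continue
            var_from, var_to, sign = canonical_transformation(var_x, var_y, cuts_x)
            if sign == 1:
                id_a, id_b = id_x, id_y
                delta = rec_y.property - rec_x.property
                src_a, src_b = rec_x.source, rec_y.source
            else:
                id_a, id_b = id_y, id_x
                delta = rec_x.property - rec_y.property
                src_a, src_b = rec_y.source, rec_x.source
            key = (id_a, id_b, context_key, var_from, var_to)
            if key not in pairs:
                pairs[key] = MatchedPair(
                    id_a=id_a,
                    id_b=id_b,
                    context_key=context_key,
                    variable_a=var_from,
                    variable_b=var_to,
                    delta=float(delta),
                    n_cuts=cuts_x,
                    source_a=src_a,
                    source_b=src_b,
                )
    return [pairs[k] for k in sorted(pairs)]


def mine_pairs(
    records: list[MoleculeRecord],
    max_cuts: int = 3,
    max_heavy_variable: int = 13,
    min_ratio_context_to_variable: float = 1.0,
    hydrogen_mode: bool = True,
) -> list[MatchedPair]:
    """Convenience: fragment every record, index, and generate pairs."""
    frags: list[Fragmentation] = []
    for rec in records:
        frags.extend(
            enumerate_fragmentations(
                rec,
                max_cuts=max_cuts,
                max_heavy_variable=max_heavy_variable,
                min_ratio_context_to_variable=min_ratio_context_to_variable,
                hydrogen_mode=hydrogen_mode,
            )
        )
    return generate_mmps(build_index(frags), records)
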