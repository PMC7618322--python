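"""Conformational collections: reading, superposition, filtering.

A collection gathers M experimentally determined conformations of close
homologs as Cα traces on a common residue grid of length L.  Residue i
carries a confidence weight w_i equal to the proportion of conformations in
which it is resolved.  Conformations are centred and superposed onto a
reference with a weight-aware least-squares (Kabsch) rotation before motion
extraction; the Kabsch optimality condition makes the summed cross products
between reference positions and any extracted displacement field vanish,
which is what later allows orienting predicted motions by zeroing angular
velocity.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

try:
    import gemmi
except ImportError:  # pragma: no cover - gemmi is a hard dependency
    gemmi = None

__all__ = [
    "ConformationalCollection",
    "FilterReport",
    "read_collection",
    "superpose",
    "select_references",
    "filter_collection",
    "pairwise_rmsd",
    "max_pairwise_rmsd",
    "write_bundle",
    "read_bundle",
    "write_member_cif",
    "write_member_pdb",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

BUNDLE_SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class RankError(ValueError):
    pass


@dataclass
class ConformationalCollection:
    """M conformations x L residues x 3 Cα coordinates (Å) on a shared grid.

    ``mask[m, i]`` is True when residue i is resolved in conformation m;
    unresolved coordinate entries are zero-filled and excluded from all
    weighted sums.  ``weights[i]`` = (# conformations resolving i) / M.
    """

    id: str
    sequence: str
    coords: np.ndarray           # (M, L, 3)
    mask: np.ndarray             # (M, L) bool
    weights: np.ndarray          # (L,)
    reference_index: int = 0
    member_ids: list = field(default_factory=list)
    superposed: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        M, L, _ = self.coords.shape
        if self.mask.shape != (M, L):
            raise ValueError("mask shape mismatch")
        if not np.all(self.mask.any(axis=1)):
            raise ValueError("every conformation needs >= 1 resolved residue")

    @property
    def n_conformations(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass
class FilterReport:
    """Outcome of the collection inclusion filters.

    ``passed`` is True iff ``failed_criteria`` is empty.
    """

    passed: bool
    max_pairwise_rmsd: float
    n_conformations: int
    length: int
    pc1_variance_fraction: float
    effective_size: float
    failed_criteria: list


# ---------------------------------------------------------------------------
# reading structure files


def _chain_ca_records(path, chain_name):
    """(seqid, one-letter aa, xyz) for the highest-occupancy Cα of each residue."""
    if gemmi is None:
        raise ImportError("gemmi is required to read structure files")
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path} contains no models")
    model = st[0]
    chain = model.find_chain(chain_name)
    if chain is None:
        raise FormatError(f"chain {chain_name!r} not found in {path}")
    records = {}
    for res in chain:
        best = None
        for atom in res:
            if atom.name != "CA":
                continue
            if best is None or atom.occ > best.occ:
                best = atom
        if best is None:
            continue
        num = res.seqid.num
        aa = THREE_TO_ONE.get(res.name.upper(), "X")
        # keep the first residue seen at a given number (altloc residues)
        if num not in records:
            records[num] = (aa, np.array([best.pos.x, best.pos.y, best.pos.z]))
    return records


def read_collection(structure_files, chain_selectors, collection_id="collection"
                    ) -> ConformationalCollection:
    """Read a set of single-chain structure files into a Cα collection.

    Residue correspondence across members uses positional mapping on the
    residue numbering shared by the close homologs (full multiple sequence
    alignment construction is out of scope): position i of the master grid
    is the i-th residue number in the sorted union of numbers observed in
    any member.  The master sequence takes, per position, the amino acid of
    the member resolving it; the default reference is the member with the
    largest resolved set (ties to the lowest index).
    """
    if len(structure_files) != len(chain_selectors):
        raise ValueError("one chain selector per structure file is required")
    per_member = [
        _chain_ca_records(p, c) for p, c in zip(structure_files, chain_selectors)
    ]
    union = sorted(set().union(*[set(r) for r in per_member]))
    if not union:
        raise AlignmentError("no Cα records found in any member")
    pos_of = {num: i for i, num in enumerate(union)}
    L, M = len(union), len(per_member)
    coords = np.zeros((M, L, 3))
    mask = np.zeros((M, L), dtype=bool)
    seq = ["X"] * L
    for m, records in enumerate(per_member):
        for num, (aa, xyz) in records.items():
            i = pos_of[num]
            coords[m, i] = xyz
            mask[m, i] = True
            if seq[i] == "X":
                seq[i] = aa
    common = mask.all(axis=0)
    if not common.any():
        raise AlignmentError("members share zero common resolved residues")
    weights = mask.mean(axis=0)
    reference_index = int(np.argmax(mask.sum(axis=1)))
    member_ids = [
        f"{os.path.basename(str(p))}:{c}"
        for p, c in zip(structure_files, chain_selectors)
    ]
    return ConformationalCollection(
        id=collection_id, sequence="".join(seq), coords=coords, mask=mask,
        weights=weights, reference_index=reference_index,
        member_ids=member_ids,
    )


# ---------------------------------------------------------------------------
# superposition


def _kabsch(ref: np.ndarray, mob: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising sum_i w_i ||R mob_i - ref_i||^2
    for already-centred point sets."""
    m = np.einsum("i,ia,ib->ab", w, ref, mob)
    u, s, vt = np.linalg.svd(m)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise RankError("degenerate (collinear) reference for superposition")
    d = np.diag([1.0, 1.0, np.sign(np.linalg.det(u @ vt))])
    return u @ d @ vt


def _centroid(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    return np.einsum("i,ia->a", w, x) / total


def superpose(collection: ConformationalCollection,
              reference_index: int | None = None) -> ConformationalCollection:
    """Centre every conformation and rotate it onto the reference.

    Each conformation is centred at its weighted centroid (weights w_i
    restricted to its resolved residues) and rotated by the weight-aware
    Kabsch rotation fitted on the residues resolved in both the member and
    the reference.  The operation is idempotent to numerical precision.
    """
    if reference_index is None:
        reference_index = collection.reference_index
    coords = collection.coords.copy()
    mask = collection.mask
    w = collection.weights
    M, L, _ = coords.shape
    ref_mask = mask[reference_index]
    if (w * ref_mask > 0).sum() < 3:
        raise RankError("reference needs >= 3 resolved weighted residues")

    # centre the reference first
    w_ref = w * ref_mask
    ref = coords[reference_index] - _centroid(coords[reference_index], w_ref)

    out = np.zeros_like(coords)
    for m in range(M):
        w_m = w * mask[m]
        centred = coords[m] - _centroid(coords[m], w_m)
        if m == reference_index:
            out[m] = centred * mask[m][:, None]
            continue
        w_fit = w * mask[m] * ref_mask
        r = _kabsch(ref, centred, w_fit)
        out[m] = (centred @ r.T) * mask[m][:, None]
    return replace(collection, coords=out, reference_index=reference_index,
                   superposed=True)


def pairwise_rmsd(collection: ConformationalCollection, i: int, j: int) -> float:
    """Weighted RMSD between members i and j after optimal superposition."""
    mask = collection.mask[i] & collection.mask[j]
    w = collection.weights * mask
    if (w > 0).sum() < 3:
        return 0.0
    a = collection.coords[i] - _centroid(collection.coords[i], w)
    b = collection.coords[j] - _centroid(collection.coords[j], w)
    r = _kabsch(a, b, w)
    diff = b @ r.T - a
    return float(np.sqrt(np.einsum("i,ia,ia->", w, diff, diff) / w.sum()))


def max_pairwise_rmsd(collection: ConformationalCollection) -> float:
    M = collection.n_conformations
    best = 0.0
    for i in range(M):
        for j in range(i + 1, M):
            best = max(best, pairwise_rmsd(collection, i, j))
    return best


def select_references(collection: ConformationalCollection, n_refs: int) -> list:
    """Reference indices for data augmentation.

    The first is the default reference (largest resolved set, ties by
    lowest index); each subsequent one maximises the pairwise RMSD to the
    previous reference among the not-yet-selected members, which maximises
    the diversity of the extracted motions.
    """
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    M = collection.n_conformations
    refs = [int(np.argmax(collection.mask.sum(axis=1)))]
    while len(refs) < min(n_refs, M):
        prev = refs[-1]
        candidates = [m for m in range(M) if m not in refs]
        rmsds = [pairwise_rmsd(collection, prev, m) for m in candidates]
        refs.append(candidates[int(np.argmax(rmsds))])
    return refs


# ---------------------------------------------------------------------------
# inclusion filters


def filter_collection(collection: ConformationalCollection, motions,
                      min_conformations: int = 5,
                      min_length: int = 30,
                      max_length: int = 1000,
                      min_rmsd: float = 2.0,
                      min_pc1_variance: float = 0.80,
                      min_effective_size: float = 12.0) -> FilterReport:
    """Apply the inclusion criteria excluding low-diversity or highly
    non-linear collections: >= 5 conformations, 30 <= L <= 1000, max
    pairwise RMSD >= 2 Å, first component carrying >= 80% of the variance,
    and an effective motion size L * kappa >= 12 residues."""
    from .motions import collectivity, variance_contribution

    failed = []
    M, L = collection.n_conformations, collection.n_residues
    if M < min_conformations:
        failed.append("min_conformations")
    if L < min_length:
        failed.append("min_length")
    if L > max_length:
        failed.append("max_length")
    rmsd = max_pairwise_rmsd(collection)
    if rmsd < min_rmsd:
        failed.append("min_rmsd")
    if motions.eigenvalues is None or len(motions.eigenvalues) == 0:
        pc1_frac, eff = float("nan"), float("nan")
        failed.append("min_pc1_variance")
        failed.append("min_effective_size")
    else:
        pc1_frac = variance_contribution(motions.eigenvalues, 0)
        kappa = collectivity(motions.component(0))
        eff = L * kappa
        if pc1_frac < min_pc1_variance:
            failed.append("min_pc1_variance")
        if eff < min_effective_size:
            failed.append("min_effective_size")
    return FilterReport(
        passed=not failed, max_pairwise_rmsd=rmsd, n_conformations=M,
        length=L, pc1_variance_fraction=pc1_frac, effective_size=eff,
        failed_criteria=failed,
    )


# ---------------------------------------------------------------------------
# collection bundle (directory) serialisation


def write_bundle(collection: ConformationalCollection, directory) -> None:
    """Write a collection as a directory: coordinates in an ``.npz`` array
    container, weights/members in delimited text, metadata in JSON."""
    os.makedirs(directory, exist_ok=True)
    np.savez(os.path.join(directory, "coords.npz"),
             coords=collection.coords, mask=collection.mask)
    with open(os.path.join(directory, "weights.tsv"), "w") as fh:
        fh.write("residue\tweight\n")
        for i, wi in enumerate(collection.weights):
            fh.write(f"{i + 1}\t{wi:.10g}\n")
    with open(os.path.join(directory, "members.tsv"), "w") as fh:
        fh.write("index\tmember_id\n")
        for m, mid in enumerate(collection.member_ids or
                                [f"member{m}" for m in range(collection.n_conformations)]):
            fh.write(f"{m + 1}\t{mid}\n")
    meta = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "id": collection.id,
        "sequence": collection.sequence,
        "reference_index": int(collection.reference_index),
        "superposed": bool(collection.superposed),
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_bundle(directory) -> ConformationalCollection:
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != BUNDLE_SCHEMA_VERSION:
        raise FormatError("unsupported bundle schema version")
    arrays = np.load(os.path.join(directory, "coords.npz"))
    members = []
    with open(os.path.join(directory, "members.tsv")) as fh:
        fh.readline()
        for line in fh:
            members.append(line.rstrip("\n").split("\t")[1])
    mask = arrays["mask"].astype(bool)
    return ConformationalCollection(
        id=meta["id"], sequence=meta["sequence"], coords=arrays["coords"],
        mask=mask, weights=mask.mean(axis=0),
        reference_index=meta["reference_index"], member_ids=members,
        superposed=meta.get("superposed", False),
    )


# ---------------------------------------------------------------------------
# writing single members back to structure files (fixtures, trajectories)


def _member_structure(collection, member_index, name="model"):
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i in range(collection.n_residues):
        if not collection.mask[member_index, i]:
            continue
        res = gemmi.Residue()
        res.name = ONE_TO_THREE.get(collection.sequence[i], "GLY")
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        x, y, z = collection.coords[member_index, i]
        atom.pos = gemmi.Position(x, y, z)
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_member_cif(collection, member_index, path) -> None:
    """Write one member of a collection as a Cα-only mmCIF file."""
    st = _member_structure(collection, member_index,
                           name=f"{collection.id}_{member_index}")
    st.make_mmcif_document().write_file(str(path))


def write_member_pdb(collection, member_index, path) -> None:
    st = _member_structure(collection, member_index,
                           name=f"{collection.id}_{member_index}")
    st.write_pdb(str(path))
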