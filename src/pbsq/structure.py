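"""Chromophore geometry: bilin harvesting, distance networks, coplanarity.

Excitation-energy-transfer (EET) pathways through a phycobilisome are
conventionally estimated from distances between the mass centers of
bilin chromophores; pairs closer than ~35 Å are considered EET-coupled.
This module extracts bilin ligands from PDB/mmCIF coordinate files
(via gemmi), computes mass-weighted centers, pairwise distance matrices,
cutoff adjacency graphs, minimal cross-group distances (e.g. rod→core),
and the out-of-B-C-plane displacement of the A and D pyrrole rings that
distinguishes bent (PUB-like) from coplanar (PCB-like) conformers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "ChromophoreSite",
    "EETGraph",
    "RingGeometry",
    "DEFAULT_LIGAND_MAP",
    "harvest_chromophores",
    "mass_center",
    "pairwise_distances",
    "build_eet_graph",
    "min_intergroup_distance",
    "coplanarity",
]

#: Ligand residue code → bilin type.  Extend per deposition; codes are
#: not standardised across entries.
DEFAULT_LIGAND_MAP: dict[str, str] = {"CYC": "PCB", "PEB": "PEB", "PUB": "PUB"}


@dataclass
class ChromophoreSite:
    """A single bilin ligand: atoms, mass center, type and group label."""

    site_id: str
    chain_id: str
    residue_name: str
    residue_number: int
    #: list of (element symbol, (x, y, z) in Å, atomic mass in Da)
    atoms: list[tuple[str, np.ndarray, float]]
    bilin_type: str = "unknown"
    group: str = "unassigned"
    mass_center: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError(f"site {self.site_id!r} has no atoms")
        if self.mass_center is None:
            self.mass_center = mass_center(self)


def mass_center(site: ChromophoreSite) -> np.ndarray:
    """Mass-weighted mean of the site's atom coordinates (Å)."""
    masses = np.array([m for _, _, m in site.atoms], dtype=float)
    coords = np.array([np.asarray(xyz, dtype=float) for _, xyz, _ in site.atoms])
    total = masses.sum()
    if total <= 0:
        raise ValueError(f"site {site.site_id!r} has zero total mass")
    return (masses[:, None] * coords).sum(axis=0) / total


def harvest_chromophores(
    structure_file: str,
    ligand_map: Mapping[str, str] | None = None,
    group_map: Mapping[str, str] | None = None,
) -> list[ChromophoreSite]:
    """Extract bilin ligand residues from a PDB or mmCIF file.

    Parameters
    ----------
    structure_file
        Path to a coordinate file readable by gemmi (PDB or mmCIF).
    ligand_map
        Residue-name → bilin-type mapping; residues whose name is not a
        key are skipped.  Defaults to :data:`DEFAULT_LIGAND_MAP`.
    group_map
        Chain-id → group label (e.g. rod or core-cylinder id); chains
        absent from the map get group ``"unassigned"``.

    Hydrogens are excluded; atomic masses come from gemmi's element
    table.  An empty result triggers a ``UserWarning`` rather than a
    silent success.
    """
    if ligand_map is None:
        ligand_map = DEFAULT_LIGAND_MAP
    if not ligand_map:
        raise ValueError("ligand_map must be non-empty")
    group_map = dict(group_map or {})

    try:
        structure = gemmi.read_structure(str(structure_file))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"could not parse coordinate file {structure_file!r}: {exc}") from exc

    sites: list[ChromophoreSite] = []
    for model in structure:
        for chain in model:
            group = group_map.get(chain.name, "unassigned")
            for residue in chain:
                if residue.name not in ligand_map:
                    continue
                atoms = [
                    (atom.element.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z]), atom.element.weight)
                    for atom in residue
                    if not atom.is_hydrogen()
                ]
                if not atoms:
                    continue
                seqid = residue.seqid.num
                sites.append(
                    ChromophoreSite(
                        site_id=f"{chain.name}/{residue.name}{seqid}",
                        chain_id=chain.name,
                        residue_name=residue.name,
                        residue_number=seqid,
                        atoms=atoms,
                        bilin_type=ligand_map[residue.name],
                        group=group,
                    )
                )
        break  # first model only; NMR-style multi-model files are not expected
    if not sites:
        warnings.warn(
            f"no residues in {structure_file!r} matched ligand_map {sorted(ligand_map)}",
            UserWarning,
            stacklevel=2,
        )
    return sites


def pairwise_distances(sites: Sequence[ChromophoreSite]) -> np.ndarray:
    """Symmetric matrix of Euclidean mass-center distances (Å)."""
    if len(sites) == 0:
        raise ValueError("need at least one site")
    centers = np.array([s.mass_center for s in sites])
    diff = centers[:, None, :] - centers[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class EETGraph:
    """Adjacency of chromophores at a distance cutoff."""

    nodes: list[str]
    distances: np.ndarray
    cutoff: float
    edges: list[tuple[str, str, float]]
    sites: list[ChromophoreSite] = field(default_factory=list, repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_eet_graph(sites: Sequence[ChromophoreSite], cutoff: float = 35.0) -> EETGraph:
    """Graph whose edges are exactly the site pairs with distance ≤ cutoff.

    The 35-Å default is the conventional upper bound for efficient
    interbilin EET; the boundary is inclusive.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be positive")
    dist = pairwise_distances(sites)
    ids = [s.site_id for s in sites]
    edges = [
        (ids[i], ids[j], float(dist[i, j]))
        for i in range(len(sites))
        for j in range(i + 1, len(sites))
        if dist[i, j] <= cutoff
    ]
    return EETGraph(nodes=ids, distances=dist, cutoff=float(cutoff), edges=edges, sites=list(sites))


def min_intergroup_distance(
    graph_or_sites: EETGraph | Sequence[ChromophoreSite],
    group_a: str,
    group_b: str,
) -> tuple[float, tuple[str, str]]:
    """Minimum mass-center distance between two groups, with the pair.

    Ties are broken by lexicographic (site_id_a, site_id_b).  Asking for
    a group against itself is an error: the statistic is cross-group by
    contract.
    """
    sites = graph_or_sites.sites if isinstance(graph_or_sites, EETGraph) else list(graph_or_sites)
    if group_a == group_b:
        raise ValueError("group_a and group_b must differ (cross-group distance)")
    a_sites = [s for s in sites if s.group == group_a]
    b_sites = [s for s in sites if s.group == group_b]
    if not a_sites:
        raise ValueError(f"no sites in group {group_a!r}")
    if not b_sites:
        raise ValueError(f"no sites in group {group_b!r}")
    best: tuple[float, tuple[str, str]] | None = None
    for sa in a_sites:
        for sb in b_sites:
            d = float(np.linalg.norm(sa.mass_center - sb.mass_center))
            key = (d, (sa.site_id, sb.site_id))
            if best is None or key < best:
                best = key
    assert best is not None
    return best


@dataclass
class RingGeometry:
    """B-C plane fit and signed A/D ring displacements for one bilin."""

    ring_atom_sets: dict[str, list[str]]
    bc_normal: np.ndarray
    bc_offset: float
    out_of_plane: dict[str, float]


def _ring_coords(site: ChromophoreSite, indices: Iterable[int], ring: str) -> np.ndarray:
    wanted = list(indices)
    if not all(isinstance(n, (int, np.integer)) for n in wanted):
        raise TypeError("ring atom subsets are given as atom indices into site.atoms")
    arr = np.array([np.asarray(site.atoms[i][1], dtype=float) for i in wanted])
    if arr.shape[0] < 3:
        raise ValueError(f"ring {ring!r} needs >=3 atoms, got {arr.shape[0]}")
    return arr


def coplanarity(site: ChromophoreSite, ring_defs: Mapping[str, Sequence[int]]) -> RingGeometry:
    """Fit the B-C pyrrole plane and measure A/D ring displacement.

    ``ring_defs`` maps ring labels ``"A" "B" "C" "D"`` to indices into
    ``site.atoms`` (atom naming varies across depositions, so subsets
    are user-supplied).  The B∪C plane is fitted by total least squares
    (smallest eigenvector of the centered covariance); ``out_of_plane``
    holds the signed perpendicular displacement of the A and D ring
    centroids.  The normal is oriented so ring A displaces positively
    (ties resolved toward +z).
    """
    for ring in ("A", "B", "C", "D"):
        if ring not in ring_defs:
            raise ValueError(f"ring_defs missing ring {ring!r}")
    bc = np.vstack(
        [_ring_coords(site, ring_defs["B"], "B"), _ring_coords(site, ring_defs["C"], "C")]
    )
    centroid = bc.mean(axis=0)
    centered = bc - centroid
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    # degenerate (collinear) atom sets have two near-zero eigenvalues
    if eigvals[1] <= 1e-10 * max(eigvals[2], 1.0):
        raise ValueError("B/C ring atoms are collinear or degenerate; plane undefined")
    normal = eigvecs[:, 0]
    normal = normal / np.linalg.norm(normal)

    cent_a = _ring_coords(site, ring_defs["A"], "A").mean(axis=0)
    cent_d = _ring_coords(site, ring_defs["D"], "D").mean(axis=0)
    disp_a = float(np.dot(cent_a - centroid, normal))
    disp_d = float(np.dot(cent_d - centroid, normal))
    if disp_a < 0 or (disp_a == 0 and normal[2] < 0):
        normal = -normal
        disp_a, disp_d = -disp_a, -disp_d
    return RingGeometry(
        ring_atom_sets={k: list(v) for k, v in ring_defs.items()},
        bc_normal=normal,
        bc_offset=float(np.dot(normal, centroid)),
        out_of_plane={"A": disp_a, "D": disp_d},
    )
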