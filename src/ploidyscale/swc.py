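"""SWC neuron reconstructions as validated rooted trees.

The SWC dialect accepted here is the standard 7-column text format
(id, type, x, y, z, radius, parent).  Structure type 1 is soma; every
other positive type is collapsed to "neurite", which is how the
downstream morphometry treats axons and dendrites alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SOMA = 1
NEURITE = 3


class SWCFormatError(ValueError):
    """Raised when an SWC file violates the structural contract."""


@dataclass
class NeuronTree:
    """Rooted tree of 3-D nodes with radii.

    Attributes
    ----------
    node_id, parent_id :
        Contiguous integer ids (root has parent ``-1``).
    node_type :
        ``SOMA`` (1) or ``NEURITE`` (3).
    xyz : (n, 3) float array, micrometres.
    radius : (n,) float array, micrometres.
    metadata : free-form dict (neuron_id, ploidy, brain_region, ...).
    """

    node_id: np.ndarray
    parent_id: np.ndarray
    node_type: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=int)
        self.parent_id = np.asarray(self.parent_id, dtype=int)
        self.node_type = np.asarray(self.node_type, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_id)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent_id < 0)[0])

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in range(self.n_nodes)}
        for i, p in enumerate(self.parent_id):
            if p >= 0:
                out[int(p)].append(i)
        return out

    def soma_mask(self) -> np.ndarray:
        return self.node_type == SOMA

    def soma_centroid(self) -> np.ndarray:
        return self.xyz[self.soma_mask()].mean(axis=0)

    def soma_radius(self) -> float:
        """Radius of the volume-equivalent sphere over all soma nodes.

        Single-node somata (the common case) return that node's radius.
        """
        r = self.radius[self.soma_mask()]
        if len(r) == 1:
            return float(r[0])
        return float(np.cbrt(np.sum(r**3)))

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise SWCFormatError("empty tree")
        roots = np.flatnonzero(self.parent_id < 0)
        if len(roots) != 1:
            raise SWCFormatError(f"expected exactly one root, found {len(roots)}")
        if np.any(self.radius <= 0):
            bad = int(np.flatnonzero(self.radius <= 0)[0])
            raise SWCFormatError(f"non-positive radius at node {bad}")
        if not np.any(self.soma_mask()):
            raise SWCFormatError("tree has no soma node")
        if self.node_type[self.root] != SOMA:
            raise SWCFormatError("root node is not soma")
        # acyclicity + connectivity: every node must reach the root
        parent = self.parent_id
        for i in range(n):
            seen = 0
            j = i
            while parent[j] >= 0:
                j = int(parent[j])
                seen += 1
                if seen > n:
                    raise SWCFormatError(f"cycle detected through node {i}")
        # soma nodes form a connected subtree containing the root
        for i in np.flatnonzero(self.soma_mask()):
            p = self.parent_id[i]
            if p >= 0 and self.node_type[p] != SOMA:
                raise SWCFormatError(
                    f"soma node {i} attached to a neurite parent {p}"
                )

    def rescaled(
        self,
        length_factor: float,
        neurite_radius_factor: float,
        soma_radius_factor: float,
    ) -> "NeuronTree":
        """Deterministic rescaling keeping the topology fixed.

        The neurite arbor is scaled uniformly about the soma centroid by
        ``length_factor`` (so every neurite-to-neurite chord scales
        exactly), then each stem subtree is rigidly translated along its
        stem ray so that the stem stays attached at the rescaled soma
        surface.  The rigid shift preserves within-subtree chords, and
        the soma-surface-referenced stem length scales exactly by
        ``length_factor`` as well.  Neurite radii scale by
        ``neurite_radius_factor`` and soma radii by ``soma_radius_factor``.
        """
        c = self.soma_centroid()
        r0 = self.soma_radius()
        soma = self.soma_mask()
        neur = ~soma
        xyz = self.xyz.copy()
        radius = self.radius.copy()
        xyz[neur] = c + length_factor * (xyz[neur] - c)
        xyz[soma] = c + soma_radius_factor * (xyz[soma] - c)

        kids = self.children()
        shift = r0 * (length_factor - soma_radius_factor)
        for i in np.flatnonzero(neur):
            p = self.parent_id[i]
            if p < 0 or not soma[p]:
                continue  # only stem children anchor a subtree
            v = self.xyz[i] - c
            d = np.linalg.norm(v)
            if d == 0:
                continue
            delta = -(v / d) * shift
            stack = [int(i)]
            while stack:
                j = stack.pop()
                xyz[j] += delta
                stack.extend(k for k in kids[j] if not soma[k])

        radius[neur] *= neurite_radius_factor
        radius[soma] *= soma_radius_factor
        meta = dict(self.metadata)
        return NeuronTree(
            self.node_id.copy(), self.parent_id.copy(), self.node_type.copy(),
            xyz, radius, meta,
        )


def read_swc(path, metadata: dict | None = None) -> NeuronTree:
    """Read a 7-column SWC file into a validated :class:`NeuronTree`.

    Node ids are remapped to contiguous 0-based integers.  Soma nodes are
    those of SWC type 1; every other structure type becomes neurite.
    """
    ids, types, xyz, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 7:
                raise SWCFormatError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(parts[0]); typ = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                par = int(parts[6])
            except ValueError as exc:
                raise SWCFormatError(f"{path}:{lineno}: unparsable field ({exc})") from None
            if r <= 0:
                raise SWCFormatError(f"{path}:{lineno}: non-positive radius {r}")
            ids.append(nid); types.append(typ)
            xyz.append((x, y, z)); radii.append(r); parents.append(par)
    if not ids:
        raise SWCFormatError(f"{path}: no nodes")
    index = {nid: i for i, nid in enumerate(ids)}
    if len(index) != len(ids):
        raise SWCFormatError(f"{path}: duplicate node ids")
    parent_idx = []
    for lineno_pos, par in enumerate(parents):
        if par == -1:
            parent_idx.append(-1)
        elif par in index:
            parent_idx.append(index[par])
        else:
            raise SWCFormatError(
                f"{path}: node {ids[lineno_pos]} references missing parent {par}"
            )
    node_type = np.where(np.asarray(types) == SOMA, SOMA, NEURITE)
    return NeuronTree(
        np.arange(len(ids)), np.asarray(parent_idx), node_type,
        np.asarray(xyz), np.asarray(radii), dict(metadata or {}),
    )


def write_swc(tree: NeuronTree, path) -> None:
    """Write the tree back out as 7-column SWC (1-based ids)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(tree.n_nodes):
            p = tree.parent_id[i]
            fh.write(
                f"{i + 1} {int(tree.node_type[i])} "
                f"{tree.xyz[i, 0]:.6f} {tree.xyz[i, 1]:.6f} {tree.xyz[i, 2]:.6f} "
                f"{tree.radius[i]:.6f} {p + 1 if p >= 0 else -1}\n"
            )
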