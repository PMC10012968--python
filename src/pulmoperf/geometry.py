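"""Synthetic lung shapes and anatomically based vascular tree generation.

The pipeline mirrors how anatomically based perfusion models are built from
imaging, but with parametric stand-ins for the image-derived pieces:

1. :func:`generate_lung_shapes` makes two half-ellipsoid lung envelopes
   (the right lung holding 52.5 % of total volume by default).
2. :func:`seed_acini` fills a shape with a quasi-uniform cloud of acinar
   seed points (jittered grid).
3. :func:`grow_volume_filling_tree` grows a bifurcating arterial tree into
   the seed cloud by recursive centroid splitting, one terminal per seed.
4. :func:`assign_strahler_radii` orders the tree (Strahler) and assigns
   diameters by a constant diameter ratio per order.
5. :func:`mirror_venous_network` mirrors the arterial tree into a venous one
   (venous diameter ratio differs), terminals co-located.
6. :func:`build_full_circulation` joins matched arterial/venous terminals
   through acinar micro-circulatory units into one closed network.

All quantities are SI (m, m^2, m^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# element type codes
ARTERY = 0
VEIN = 1

TYPE_NAMES = {ARTERY: "artery", VEIN: "vein"}
TYPE_CODES = {v: k for k, v in TYPE_NAMES.items()}

#: Table-of-record vessel cross-sections for the macro (MPA/LPA/RPA) domain, m^2
MPA_AREA = 7.72e-4
LPA_AREA = 3.77e-4
RPA_AREA = 3.54e-4

#: anatomical acinar count the full-scale model resolves
N_ACINI_REFERENCE = 30676

RIGHT_LUNG_VOLUME_FRACTION = 0.525


def _ellipsoid_axes_for_volume(base_axes, volume):
    """Scale base semi-axes isotropically so the half-ellipsoid has `volume`."""
    base = np.asarray(base_axes, dtype=float)
    v0 = (2.0 / 3.0) * np.pi * np.prod(base)
    return base * (volume / v0) ** (1.0 / 3.0)


@dataclass(frozen=True)
class LungShape:
    """Half-ellipsoid lung envelope, clipped at its basal (equatorial) plane.

    Membership: ((p - center)/semi_axes)^2 summed <= 1 and p_z >= center_z.
    """

    side: str  # "left" | "right"
    center: np.ndarray
    semi_axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, float))
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")

    @property
    def volume(self) -> float:
        return (2.0 / 3.0) * np.pi * float(np.prod(self.semi_axes))

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        u = (p - self.center) / self.semi_axes
        inside = (u * u).sum(axis=1) <= 1.0
        inside &= p[:, 2] >= self.center[2]
        return inside if p.ndim > 1 else inside[0]

    @property
    def hilum(self) -> np.ndarray:
        """Feeding-vessel entry point: 60 % of cranio-caudal height, ventral
        of center, just inside the mediastinal (medial) surface.

        The ventral offset differs between sides: the right lung carries
        more of its tissue dorsal of its hilum than the left does, which is
        what redistributes flow toward the right lung in supine and toward
        the left in prone once the feeding-trunk hydrostatic head is handled
        upstream of the hilum.
        """
        if self.side == "right":
            frac = np.array([-0.68, -0.38, 0.60])  # toward midline, ventral
        else:
            frac = np.array([0.73, -0.22, 0.60])
        return self.center + self.semi_axes * frac

    def bounding_box(self):
        lo = self.center - self.semi_axes
        lo[2] = self.center[2]
        hi = self.center + self.semi_axes
        return lo, hi


# One-time anatomical proportions: the right lung is wider, deeper
# (dorso-ventrally) and shorter than the left.  The dorso-ventral center
# offsets (left ventral-weighted, right dorsal-weighted) encode the different
# disposition of tissue relative to the heart that redistributes flow between
# lungs in prone vs supine postures.
_LEFT_BASE_AXES = (0.060, 0.090, 0.168)
_RIGHT_BASE_AXES = (0.070, 0.095, 0.1508)
_LEFT_CENTER = (-0.075, -0.008, 0.0)
_RIGHT_CENTER = (0.075, 0.008, 0.0)

#: heart-level reference points (anatomical coordinates, m)
HEART_INLET = np.array([0.0, -0.030, 0.070])  # main pulmonary artery root
HEART_JUNCTION = np.array([0.0, -0.025, 0.080])  # MPA bifurcation
VENOUS_JUNCTION = np.array([0.0, -0.025, 0.060])  # venous confluence
VENOUS_OUTLET = np.array([0.0, -0.030, 0.050])  # left atrium


def generate_lung_shapes(
    total_volume: float = 4.0e-3,
    right_fraction: float = RIGHT_LUNG_VOLUME_FRACTION,
) -> tuple[LungShape, LungShape]:
    """Create (left, right) half-ellipsoid lung shapes.

    The right lung receives ``right_fraction`` of ``total_volume`` exactly
    (the semi-axes are scaled to the requested volume analytically).
    """
    if total_volume <= 0:
        raise ValueError("total_volume must be positive")
    if not 0.0 < right_fraction < 1.0:
        raise ValueError("right_fraction must lie in (0, 1)")
    v_right = right_fraction * total_volume
    v_left = total_volume - v_right
    left = LungShape(
        side="left",
        center=np.array(_LEFT_CENTER),
        semi_axes=_ellipsoid_axes_for_volume(_LEFT_BASE_AXES, v_left),
    )
    right = LungShape(
        side="right",
        center=np.array(_RIGHT_CENTER),
        semi_axes=_ellipsoid_axes_for_volume(_RIGHT_BASE_AXES, v_right),
    )
    return left, right


@dataclass(frozen=True)
class SeedPointSet:
    """Quasi-uniform acinar seed points inside one lung shape."""

    points: np.ndarray
    shape: LungShape

    def __len__(self):
        return len(self.points)


def seed_acini(shape: LungShape, n: int, rng_seed: int = 0) -> SeedPointSet:
    """Fill `shape` with exactly `n` quasi-uniform points (grid + jitter).

    The grid is densified until it holds at least `n` in-shape points; jitter
    is uniform within +/-20 % of the grid spacing (points jittered out of the
    shape fall back to their unjittered location).
    """
    if n < 1:
        raise ValueError("need at least one seed point")
    rng = np.random.default_rng(rng_seed)
    lo, hi = shape.bounding_box()
    spacing = (shape.volume / n) ** (1.0 / 3.0)
    for _ in range(60):
        axes = [np.arange(lo[i] + 0.5 * spacing, hi[i], spacing) for i in range(3)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        inside = shape.contains(grid)
        pts = grid[inside]
        if len(pts) >= n:
            break
        spacing *= 0.95
    else:  # pragma: no cover - spacing shrink always terminates in practice
        raise RuntimeError("could not densify seed grid enough")
    jitter = rng.uniform(-0.2 * spacing, 0.2 * spacing, size=pts.shape)
    moved = pts + jitter
    ok = shape.contains(moved)
    pts = np.where(ok[:, None], moved, pts)
    if len(pts) > n:
        keep = np.sort(rng.choice(len(pts), size=n, replace=False))
        pts = pts[keep]
    return SeedPointSet(points=pts, shape=shape)


@dataclass(frozen=True)
class TreeGrowthParams:
    """Controls for the volume-filling branching recursion."""

    length_fraction: float = 0.4  # branch length as fraction of node->centroid
    branch_angle_limit: float = 60.0  # deg, child vs parent direction
    min_branch_length: float = 1.2e-3  # m

    def __post_init__(self):
        if not 0.0 < self.length_fraction < 1.0:
            raise ValueError("length_fraction must lie in (0, 1)")


@dataclass
class VesselNetwork:
    """Graph of vessel centerline elements (struct-of-arrays).

    Elements are directed in the nominal flow direction: arteries root->leaf,
    veins leaf->root.  Acinar micro-circulatory units are kept in a separate
    table (``acinus_*`` arrays) joining matched arterial/venous terminals;
    they are not centerline elements.
    """

    node_xyz: np.ndarray  # (N, 3)
    elem_node_in: np.ndarray  # (E,)
    elem_node_out: np.ndarray  # (E,)
    elem_type: np.ndarray  # (E,) ARTERY | VEIN
    elem_D0: np.ndarray  # (E,) unstrained diameter, m
    elem_order: np.ndarray  # (E,) Strahler order (0 = unassigned)
    elem_generation: np.ndarray  # (E,)
    inlet_node: int = -1
    outlet_node: int = -1
    interface_nodes: dict = field(default_factory=dict)  # {"LPA": id, "RPA": id}
    macro_element_ids: np.ndarray = field(default_factory=lambda: np.array([], int))
    # acinus table (all same length = number of acini)
    acinus_art_node: np.ndarray = field(default_factory=lambda: np.array([], int))
    acinus_ven_node: np.ndarray = field(default_factory=lambda: np.array([], int))
    acinus_art_elem: np.ndarray = field(default_factory=lambda: np.array([], int))
    acinus_lung: np.ndarray = field(default_factory=lambda: np.array([], "U8"))
    # relative capillary surface area per acinus (mean 1); scales each
    # acinus' share of the whole-lung sheet surface area
    acinus_sa_weight: np.ndarray = field(default_factory=lambda: np.array([], float))

    @property
    def n_nodes(self) -> int:
        return len(self.node_xyz)

    @property
    def n_elements(self) -> int:
        return len(self.elem_node_in)

    @property
    def n_acini(self) -> int:
        return len(self.acinus_art_node)

    @property
    def elem_length(self) -> np.ndarray:
        d = self.node_xyz[self.elem_node_out] - self.node_xyz[self.elem_node_in]
        return np.linalg.norm(d, axis=1)

    @property
    def acinus_xyz(self) -> np.ndarray:
        return self.node_xyz[self.acinus_art_node]

    def element_midpoints(self) -> np.ndarray:
        return 0.5 * (self.node_xyz[self.elem_node_in] + self.node_xyz[self.elem_node_out])

    def subgraph_element_ids(self, types) -> np.ndarray:
        codes = [TYPE_CODES[t] if isinstance(t, str) else t for t in np.atleast_1d(types)]
        return np.flatnonzero(np.isin(self.elem_type, codes))

    def validate(self) -> None:
        if np.any(self.elem_length <= 0):
            raise ValueError("zero-length element present")
        if np.any(self.elem_D0 <= 0):
            raise ValueError("non-positive diameter present")

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for i in range(self.n_elements):
            g.add_edge(int(self.elem_node_in[i]), int(self.elem_node_out[i]), elem=i)
        return g


class _Builder:
    """Mutable accumulator for nodes and elements."""

    def __init__(self):
        self.xyz: list[np.ndarray] = []
        self.e_in: list[int] = []
        self.e_out: list[int] = []
        self.e_type: list[int] = []
        self.e_D0: list[float] = []
        self.e_gen: list[int] = []

    def add_node(self, pos) -> int:
        self.xyz.append(np.asarray(pos, float))
        return len(self.xyz) - 1

    def add_element(self, n_in, n_out, etype, d0, gen) -> int:
        self.e_in.append(n_in)
        self.e_out.append(n_out)
        self.e_type.append(etype)
        self.e_D0.append(d0)
        self.e_gen.append(gen)
        return len(self.e_in) - 1

    def finish(self, **kwargs) -> VesselNetwork:
        return VesselNetwork(
            node_xyz=np.array(self.xyz),
            elem_node_in=np.array(self.e_in, int),
            elem_node_out=np.array(self.e_out, int),
            elem_type=np.array(self.e_type, int),
            elem_D0=np.array(self.e_D0, float),
            elem_order=np.zeros(len(self.e_in), int),
            elem_generation=np.array(self.e_gen, int),
            **kwargs,
        )


def area_to_diameter(area: float) -> float:
    return float(np.sqrt(4.0 * area / np.pi))


def initial_macro_tree() -> VesselNetwork:
    """Fixed template: MPA trunk splitting to LPA/RPA stubs.

    Stub cross-sections match the recorded macro-vessel areas; the stub end
    nodes are the 1D/macro interface nodes and the growth origins for the two
    lung trees.
    """
    left, right = generate_lung_shapes()
    b = _Builder()
    n_inlet = b.add_node(HEART_INLET)
    n_junc = b.add_node(HEART_JUNCTION)
    n_l = b.add_node(left.hilum)
    n_r = b.add_node(right.hilum)
    e_mpa = b.add_element(n_inlet, n_junc, ARTERY, area_to_diameter(MPA_AREA), 0)
    e_lpa = b.add_element(n_junc, n_l, ARTERY, area_to_diameter(LPA_AREA), 1)
    e_rpa = b.add_element(n_junc, n_r, ARTERY, area_to_diameter(RPA_AREA), 1)
    net = b.finish(
        inlet_node=n_inlet,
        interface_nodes={"LPA": n_l, "RPA": n_r},
        macro_element_ids=np.array([e_mpa, e_lpa, e_rpa], int),
    )
    return net


def _rotate_toward(v, ref, max_angle_rad):
    """Rotate direction `v` toward `ref` so the angle between them is at most
    `max_angle_rad`.  Both must be unit vectors."""
    c = float(np.clip(np.dot(v, ref), -1.0, 1.0))
    ang = np.arccos(c)
    if ang <= max_angle_rad:
        return v
    # component of v orthogonal to ref
    perp = v - c * ref
    n = np.linalg.norm(perp)
    if n < 1e-12:  # anti-parallel: pick any orthogonal direction
        perp = np.cross(ref, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(ref, [0.0, 1.0, 0.0])
        n = np.linalg.norm(perp)
    perp /= n
    return np.cos(max_angle_rad) * ref + np.sin(max_angle_rad) * perp


def grow_volume_filling_tree(
    initial_tree: VesselNetwork,
    seeds: SeedPointSet,
    params: TreeGrowthParams = TreeGrowthParams(),
    rng_seed: int = 0,
    root_key: str | None = None,
) -> VesselNetwork:
    """Grow a bifurcating tree from an interface node into a seed cloud.

    Each recursion step splits a terminal's seed subset by the plane that
    contains the parent branch direction and passes through the subset
    centroid, then extends a branch from the terminal toward each half's
    centroid (``length_fraction`` of the distance, clamped by the branching
    angle limit and the minimum branch length).  Singleton subsets close with
    a terminal element ending exactly at the seed point (acinus attachment).

    Returns a new network containing the initial tree plus the grown branches
    for this lung.  Deterministic for a fixed ``rng_seed``.
    """
    shape = seeds.shape
    if root_key is None:
        root_key = "LPA" if shape.side == "left" else "RPA"
    root_node = initial_tree.interface_nodes[root_key]
    root_pos = initial_tree.node_xyz[root_node]

    # copy existing network into a builder
    b = _Builder()
    b.xyz = [p.copy() for p in initial_tree.node_xyz]
    b.e_in = list(initial_tree.elem_node_in)
    b.e_out = list(initial_tree.elem_node_out)
    b.e_type = list(initial_tree.elem_type)
    b.e_D0 = list(initial_tree.elem_D0)
    b.e_gen = list(initial_tree.elem_generation)

    pts = seeds.points
    # root direction: along the feeding stub, or toward the cloud centroid
    feed = [i for i in range(initial_tree.n_elements)
            if initial_tree.elem_node_out[i] == root_node]
    if feed:
        e = feed[0]
        d0 = initial_tree.node_xyz[initial_tree.elem_node_out[e]] - \
            initial_tree.node_xyz[initial_tree.elem_node_in[e]]
    else:
        d0 = pts.mean(axis=0) - root_pos
    d0 = d0 / np.linalg.norm(d0)

    max_ang = np.deg2rad(params.branch_angle_limit)
    term_elems: list[int] = []
    term_seed_idx: list[int] = []
    pruned = 0

    # stack of (node_id, unit direction, seed index array, generation)
    stack = [(root_node, d0, np.arange(len(pts)), 1)]
    placeholder_D = 1e-3  # overwritten by assign_strahler_radii
    while stack:
        node, direction, idx, gen = stack.pop()
        if len(idx) == 0:
            pruned += 1
            continue
        npos = b.xyz[node]
        if len(idx) == 1:
            target = pts[idx[0]]
            v = target - npos
            if np.linalg.norm(v) < 1e-9:  # seed coincides with node
                target = npos + 1e-4 * direction
            nn = b.add_node(target)
            e = b.add_element(node, nn, ARTERY, placeholder_D, gen)
            term_elems.append(e)
            term_seed_idx.append(int(idx[0]))
            continue
        sub = pts[idx]
        c = sub.mean(axis=0)
        u = c - npos
        normal = np.cross(direction, u)
        nn_norm = np.linalg.norm(normal)
        groups = None
        if nn_norm > 1e-12:
            side = (sub - c) @ (normal / nn_norm) > 0.0
            if side.any() and (~side).any():
                groups = (idx[side], idx[~side])
        if groups is None:
            # degenerate (colinear) subset: split at median of the longest axis
            spans = sub.max(axis=0) - sub.min(axis=0)
            ax = int(np.argmax(spans))
            med = np.median(sub[:, ax])
            side = sub[:, ax] > med
            if not side.any() or not (~side).any():
                order = np.argsort(sub[:, ax], kind="stable")
                half = len(order) // 2
                side = np.zeros(len(sub), bool)
                side[order[half:]] = True
            groups = (idx[side], idx[~side])
        for g_idx in groups:
            cg = pts[g_idx].mean(axis=0)
            v = cg - npos
            dist = np.linalg.norm(v)
            if dist < 1e-12:
                pruned += len(g_idx)
                continue
            vdir = v / dist
            vdir = _rotate_toward(vdir, direction, max_ang)
            length = max(params.length_fraction * dist, params.min_branch_length)
            new_pos = npos + length * vdir
            # keep internal branch points inside the host shape
            for _ in range(8):
                if shape.contains(new_pos[None, :])[0] or length <= params.min_branch_length:
                    break
                length = max(0.7 * length, params.min_branch_length)
                new_pos = npos + length * vdir
            nn = b.add_node(new_pos)
            b.add_element(node, nn, ARTERY, placeholder_D, gen)
            stack.append((nn, vdir, g_idx, gen + 1))

    net = b.finish(
        inlet_node=initial_tree.inlet_node,
        outlet_node=initial_tree.outlet_node,
        interface_nodes=dict(initial_tree.interface_nodes),
        macro_element_ids=initial_tree.macro_element_ids.copy(),
        acinus_art_node=np.concatenate(
            [initial_tree.acinus_art_node,
             np.array([b.e_out[e] for e in term_elems], int)]),
        acinus_ven_node=np.concatenate(
            [initial_tree.acinus_ven_node, np.full(len(term_elems), -1, int)]),
        acinus_art_elem=np.concatenate(
            [initial_tree.acinus_art_elem, np.array(term_elems, int)]),
        acinus_lung=np.concatenate(
            [initial_tree.acinus_lung, np.full(len(term_elems), shape.side, "U8")]),
        acinus_sa_weight=np.concatenate(
            [initial_tree.acinus_sa_weight, np.ones(len(term_elems))]),
    )
    net.pruned_count = pruned  # type: ignore[attr-defined]
    return net


def _children_map(net: VesselNetwork, elem_ids: np.ndarray) -> dict[int, list[int]]:
    by_in: dict[int, list[int]] = {}
    for e in elem_ids:
        by_in.setdefault(int(net.elem_node_in[e]), []).append(int(e))
    return {e: by_in.get(int(net.elem_node_out[e]), []) for e in map(int, elem_ids)}


def strahler_orders(net: VesselNetwork, elem_ids: np.ndarray) -> dict[int, int]:
    """Strahler order per element, computed leaf -> root over a subtree."""
    children = _children_map(net, elem_ids)
    order: dict[int, int] = {}
    # process in reverse creation order: parents are always created before
    # children by the growth recursion, so reversed id order is child-first
    for e in sorted(map(int, elem_ids), reverse=True):
        kids = children[e]
        if not kids:
            order[e] = 1
        else:
            kid_orders = [order[k] for k in kids]
            m = max(kid_orders)
            order[e] = m + 1 if kid_orders.count(m) >= 2 else m
    return order


def assign_strahler_radii(
    tree: VesselNetwork,
    inlet_diameter: float,
    ratio: float,
    root_elem: int | None = None,
    diameter_cv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VesselNetwork:
    """Assign diameters D0(order) = inlet_diameter * ratio**(order - max_order)
    over the subtree rooted at ``root_elem`` (whole network if omitted).

    ``diameter_cv`` adds seeded log-normal within-order scatter (coefficient
    of variation of diameter about the order mean), emulating the caliber
    variability of cast morphometry; the root keeps the inlet diameter
    exactly and diameters are clamped non-increasing root -> leaf so the
    scatter never inverts the hierarchy.

    Raises if the subtree is not acyclic or ``ratio <= 1``.
    """
    if ratio <= 1.0:
        raise ValueError("Strahler diameter ratio must exceed 1")
    if root_elem is None:
        elem_ids = np.arange(tree.n_elements)
    else:
        elem_ids = _descendant_elements(tree, root_elem)
    _check_acyclic(tree, elem_ids)
    order = strahler_orders(tree, elem_ids)
    max_order = max(order.values())
    D0 = tree.elem_D0.copy()
    orders = tree.elem_order.copy()
    sigma = np.sqrt(np.log1p(diameter_cv**2))
    for e, o in order.items():
        orders[e] = o
        d = inlet_diameter * ratio ** (o - max_order)
        if sigma > 0 and o != max_order:
            d *= np.exp(rng.normal(0.0, sigma)) if rng is not None else 1.0
        D0[e] = d
    # enforce root->leaf monotonicity (parents precede children by id)
    by_out = {int(tree.elem_node_out[e]): int(e) for e in elem_ids}
    for e in sorted(map(int, elem_ids)):
        p = by_out.get(int(tree.elem_node_in[e]))
        if p is not None:
            D0[e] = min(D0[e], D0[p])
    return replace(tree, elem_D0=D0, elem_order=orders)


def _descendant_elements(net: VesselNetwork, root_elem: int) -> np.ndarray:
    by_in: dict[int, list[int]] = {}
    for e in range(net.n_elements):
        by_in.setdefault(int(net.elem_node_in[e]), []).append(e)
    out = []
    stack = [int(root_elem)]
    while stack:
        e = stack.pop()
        out.append(e)
        stack.extend(by_in.get(int(net.elem_node_out[e]), []))
    return np.array(sorted(out), int)


def _check_acyclic(net: VesselNetwork, elem_ids: np.ndarray) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for e in elem_ids:
        g.add_edge(int(net.elem_node_in[e]), int(net.elem_node_out[e]))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("cycle detected in vessel tree")


VENOUS_STRAHLER_RATIO = 1.56
ARTERIAL_STRAHLER_RATIO = 1.52


def mirror_venous_network(arterial: VesselNetwork,
                          ratio: float = VENOUS_STRAHLER_RATIO,
                          diameter_cv: float = 0.0,
                          rng: np.random.Generator | None = None) -> VesselNetwork:
    """Mirror the arterial network into a venous one.

    Topology and node positions are copied; element directions are reversed
    (veins flow leaf -> root); diameters are re-assigned from the same Strahler
    orders using the venous diameter ratio.  The venous root of each lung is
    sized so that terminal venules match their arterial counterparts, i.e.
    root_D_vein = root_D_artery * (ratio_vein / ratio_artery)^(order span);
    with the larger venous ratio this makes veins at least as wide as the
    companion artery at every order, consistent with venous morphometry and
    with physiological (sub-arterial) venous resistance.  Terminals are
    co-located with the arterial terminals.  The mirrored trunk drains to a
    venous outlet at the left atrium.
    """
    n = arterial.n_nodes
    xyz = arterial.node_xyz.copy()
    # shift the mirrored heart-side nodes caudally so the venous trunk is
    # geometrically distinct from the arterial one
    xyz_v = xyz.copy()
    xyz_v[arterial.inlet_node] = VENOUS_OUTLET
    junc_nodes = set(arterial.elem_node_out[list(arterial.macro_element_ids)]) | \
        set(arterial.elem_node_in[list(arterial.macro_element_ids)])
    for nd in junc_nodes - {arterial.inlet_node,
                            *arterial.interface_nodes.values()}:
        xyz_v[nd] = VENOUS_JUNCTION

    orders = arterial.elem_order
    root_D = {}
    for key, node in arterial.interface_nodes.items():
        roots = [e for e in range(arterial.n_elements)
                 if arterial.elem_node_in[e] == node]
        for r in roots:
            sub = _descendant_elements(arterial, r)
            o_root = orders[r]
            root_D[r] = (sub, arterial.elem_D0[r], o_root)
    D0 = arterial.elem_D0.copy()
    sigma = np.sqrt(np.log1p(diameter_cv**2))
    for r, (sub, d_root, o_root) in root_D.items():
        d_root_ven = d_root * (ratio / ARTERIAL_STRAHLER_RATIO) ** (o_root - 1)
        D0[sub] = d_root_ven * ratio ** (orders[sub].astype(float) - o_root)
        if sigma > 0 and rng is not None:
            scatter = np.exp(rng.normal(0.0, sigma, size=len(sub)))
            scatter[orders[sub] == o_root] = 1.0  # root keeps its caliber
            D0[sub] = D0[sub] * scatter
        # monotonic root -> leaf, mirroring the arterial clamp
        by_out = {int(arterial.elem_node_out[e]): int(e) for e in sub}
        for e in sorted(map(int, sub)):
            p = by_out.get(int(arterial.elem_node_in[e]))
            if p is not None:
                D0[e] = min(D0[e], D0[p])

    ven = VesselNetwork(
        node_xyz=xyz_v,
        elem_node_in=arterial.elem_node_out.copy(),  # reversed direction
        elem_node_out=arterial.elem_node_in.copy(),
        elem_type=np.full(arterial.n_elements, VEIN, int),
        elem_D0=D0,
        elem_order=orders.copy(),
        elem_generation=arterial.elem_generation.copy(),
        inlet_node=-1,
        outlet_node=arterial.inlet_node,  # atrium replaces the MPA root
        interface_nodes={},
        acinus_art_node=np.array([], int),
        acinus_ven_node=arterial.acinus_art_node.copy(),
        acinus_art_elem=np.array([], int),
        acinus_lung=arterial.acinus_lung.copy(),
    )
    return ven


def build_full_circulation(arterial: VesselNetwork,
                           venous: VesselNetwork,
                           ladder_template=None) -> VesselNetwork:
    """Join arterial and venous trees through acinar units into one network.

    Arterial terminal *k* is matched with venous terminal *k* (they are
    co-located by construction of :func:`mirror_venous_network`); each pair is
    bridged by one acinar micro-circulatory unit (the ladder template, solved
    by the flow solver).  Venous nodes are renumbered after arterial ones.
    """
    if arterial.n_acini != len(venous.acinus_ven_node):
        raise ValueError("arterial and venous terminal counts do not match")
    off = arterial.n_nodes
    node_xyz = np.vstack([arterial.node_xyz, venous.node_xyz])
    net = VesselNetwork(
        node_xyz=node_xyz,
        elem_node_in=np.concatenate([arterial.elem_node_in, venous.elem_node_in + off]),
        elem_node_out=np.concatenate([arterial.elem_node_out, venous.elem_node_out + off]),
        elem_type=np.concatenate([arterial.elem_type, venous.elem_type]),
        elem_D0=np.concatenate([arterial.elem_D0, venous.elem_D0]),
        elem_order=np.concatenate([arterial.elem_order, venous.elem_order]),
        elem_generation=np.concatenate([arterial.elem_generation, venous.elem_generation]),
        inlet_node=arterial.inlet_node,
        outlet_node=venous.outlet_node + off,
        interface_nodes=dict(arterial.interface_nodes),
        # only the arterial MPA/LPA/RPA can be handed to the macro model;
        # the mirrored venous trunk always belongs to the 1D domain
        macro_element_ids=arterial.macro_element_ids.copy(),
        acinus_art_node=arterial.acinus_art_node.copy(),
        acinus_ven_node=venous.acinus_ven_node + off,
        acinus_art_elem=arterial.acinus_art_elem.copy(),
        acinus_lung=arterial.acinus_lung.copy(),
        acinus_sa_weight=(arterial.acinus_sa_weight.copy()
                          if len(arterial.acinus_sa_weight)
                          else np.ones(arterial.n_acini)),
    )
    net.validate()
    return net


#: within-order diameter coefficient of variation emulating cast morphometry
DIAMETER_SCATTER_CV = 0.15
#: coefficient of variation of acinar capillary surface area (acinar size)
ACINAR_SIZE_CV = 0.30


def build_circulation(
    n_acini: int = 10000,
    total_volume: float = 4.0e-3,
    right_fraction: float = RIGHT_LUNG_VOLUME_FRACTION,
    growth_params: TreeGrowthParams = TreeGrowthParams(),
    diameter_cv: float = DIAMETER_SCATTER_CV,
    acinar_size_cv: float = ACINAR_SIZE_CV,
    rng_seed: int = 0,
) -> VesselNetwork:
    """End-to-end network generation: shapes -> seeds -> arterial trees ->
    Strahler radii (with within-order scatter) -> mirrored veins -> closed
    circulation.

    Seed counts per lung are proportional to lung volume (right lung gets
    ``round(n_acini * right_fraction)``).  Deterministic for a fixed
    ``rng_seed``.
    """
    left, right = generate_lung_shapes(total_volume, right_fraction)
    n_right = int(round(n_acini * right_fraction))
    n_left = n_acini - n_right
    net = initial_macro_tree()
    seeds_l = seed_acini(left, n_left, rng_seed=rng_seed * 2 + 1)
    seeds_r = seed_acini(right, n_right, rng_seed=rng_seed * 2 + 2)
    net = grow_volume_filling_tree(net, seeds_l, growth_params, rng_seed=rng_seed)
    net = grow_volume_filling_tree(net, seeds_r, growth_params, rng_seed=rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 7]))
    # Strahler diameters per lung, anchored at each feeding stub's diameter
    for key, area in (("LPA", LPA_AREA), ("RPA", RPA_AREA)):
        node = net.interface_nodes[key]
        roots = [e for e in range(net.n_elements)
                 if net.elem_node_in[e] == node and e not in set(net.macro_element_ids)]
        for r in roots:
            net = assign_strahler_radii(
                net, area_to_diameter(area), ARTERIAL_STRAHLER_RATIO,
                root_elem=r, diameter_cv=diameter_cv, rng=rng)
    # macro stubs keep area-derived diameters and get the max order + 1
    trunk_order = int(net.elem_order.max()) + 1
    orders = net.elem_order.copy()
    orders[net.macro_element_ids] = trunk_order
    net = replace(net, elem_order=orders)
    ven = mirror_venous_network(net, diameter_cv=diameter_cv, rng=rng)
    full = build_full_circulation(net, ven)
    if acinar_size_cv > 0:
        # acinar-size heterogeneity: log-normal capillary surface share per
        # acinus, normalized so the whole-lung surface area is preserved
        sig = np.sqrt(np.log1p(acinar_size_cv**2))
        w = rng.lognormal(mean=0.0, sigma=sig, size=full.n_acini)
        full.acinus_sa_weight = w / w.mean()
    return full
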