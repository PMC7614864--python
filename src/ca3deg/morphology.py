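"""Neuronal morphologies: SWC I/O, synthetic reduced trees, cable discretization.

A morphology is held as a :class:`SectionTree` (unbranched sections of 3D
sample points, soma/apical/basal labelled) and turned into a
:class:`CompartmentalModel` of iso-potential compartments via the d_lambda
rule: every section is split into the smallest odd number of segments such
that no segment is longer than ``d_lambda`` times the AC length constant at
a reference frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Section",
    "SectionTree",
    "CompartmentalModel",
    "load_swc",
    "write_swc",
    "build_synthetic_morphology",
    "discretize",
    "lambda_f",
]

_SWC_TYPE_TO_LABEL = {1: "soma", 3: "basal", 4: "apical"}
_LABEL_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_LABEL.items()}


class SWCError(ValueError):
    """Malformed or structurally invalid SWC content."""


@dataclass
class Section:
    """Unbranched run of 3D samples.

    ``points`` is an (N, 4) array of x, y, z, diameter in micrometres. For a
    non-root section the first point is the attachment point on the parent
    (shared coordinate, not duplicated on SWC export).
    """

    id: int
    parent: int  # section id of parent, -1 for root
    label: str  # soma | apical | basal
    points: np.ndarray

    @property
    def length(self) -> float:
        """Arc length in micrometres."""
        p = self.points[:, :3]
        if len(p) < 2:
            # single-sample soma: sphere encoded by its diameter
            return float(self.points[0, 3])
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))

    def mean_diam(self) -> float:
        d = self.points[:, 3]
        if len(d) == 1:
            return float(d[0])
        seg = np.linalg.norm(np.diff(self.points[:, :3], axis=0), axis=1)
        mid = 0.5 * (d[:-1] + d[1:])
        tot = seg.sum()
        if tot <= 0:
            return float(d.mean())
        return float(np.sum(mid * seg) / tot)


@dataclass
class SectionTree:
    """Rooted tree of sections; single soma root, acyclic parent links."""

    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {s.id: s for s in self.sections}
        self.validate()

    def __len__(self) -> int:
        return len(self.sections)

    def section(self, sid: int) -> Section:
        return self._by_id[sid]

    def children(self, sid: int) -> list[Section]:
        return [s for s in self.sections if s.parent == sid]

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent == -1)

    def validate(self) -> None:
        roots = [s for s in self.sections if s.parent == -1]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root section, found {len(roots)}")
        if roots[0].label != "soma":
            raise SWCError("root section must be of type soma")
        ids = set(self._by_id)
        for s in self.sections:
            if s.parent != -1 and s.parent not in ids:
                raise SWCError(f"section {s.id} references missing parent {s.parent}")
            if np.any(s.points[:, 3] <= 0):
                raise SWCError(f"section {s.id} has non-positive diameter")
            if s.length <= 0:
                raise SWCError(f"section {s.id} has non-positive length")
        # acyclicity: walk every section to the root
        for s in self.sections:
            seen, cur = set(), s
            while cur.parent != -1:
                if cur.id in seen:
                    raise SWCError("cycle in parent links")
                seen.add(cur.id)
                cur = self._by_id[cur.parent]

    def topological_order(self) -> list[Section]:
        """Sections ordered parent-before-child."""
        order: list[Section] = []
        stack = [self.root]
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(sorted(self.children(s.id), key=lambda c: -c.id))
        return order

    def total_area(self) -> float:
        """Membrane area in µm² (cylindrical frusta; soma as equivalent cylinder)."""
        area = 0.0
        for s in self.sections:
            if s.label == "soma" and len(s.points) == 1:
                d = s.points[0, 3]
                area += math.pi * d * d  # sphere == equivalent cylinder L=d
                continue
            p, d = s.points[:, :3], s.points[:, 3]
            seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
            area += float(np.sum(math.pi * 0.5 * (d[:-1] + d[1:]) * seg))
        return area


def load_swc(path) -> SectionTree:
    """Read a standard 7-column SWC file into a :class:`SectionTree`.

    Supports the soma/basal/apical type codes 1/3/4; '#' comments and blank
    lines are ignored. Raises :class:`SWCError` naming the offending line on
    malformed rows and on structural defects (missing parents, multiple
    roots).
    """
    samples: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                n = int(cols[0])
                t = int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                par = int(cols[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if t not in _SWC_TYPE_TO_LABEL:
                raise SWCError(
                    f"line {lineno}: unsupported SWC type {t} "
                    "(soma=1, basal=3, apical=4 supported; models carry no axon)"
                )
            if n in samples:
                raise SWCError(f"line {lineno}: duplicate sample id {n}")
            samples[n] = (t, x, y, z, r, par)

    if not samples:
        raise SWCError("empty SWC file")
    roots = [n for n, s in samples.items() if s[5] == -1]
    if len(roots) != 1:
        raise SWCError(f"expected exactly one root sample, found {len(roots)}")
    for n, s in samples.items():
        if s[5] != -1 and s[5] not in samples:
            raise SWCError(f"sample {n} references missing parent {s[5]}")

    children: dict[int, list[int]] = {n: [] for n in samples}
    for n, s in samples.items():
        if s[5] != -1:
            children[s[5]].append(n)
    for kids in children.values():
        kids.sort()

    def pt(n: int) -> list[float]:
        t, x, y, z, r, _ = samples[n]
        return [x, y, z, 2.0 * r]

    root = roots[0]
    if samples[root][0] != 1:
        raise SWCError("root sample must be of soma type (code 1)")

    # all soma samples collapse into one root section (the 1- and 3-point
    # soma conventions, and contoured somata, stay a single section)
    soma_ids = sorted(n for n, s in samples.items() if s[0] == 1)
    for n in soma_ids:
        par = samples[n][5]
        if par != -1 and samples[par][0] != 1:
            raise SWCError(f"soma sample {n} has a non-soma parent")
    sections: list[Section] = [
        Section(0, -1, "soma",
                np.asarray([pt(n) for n in soma_ids], dtype=float))
    ]
    next_sid = 1

    # split the dendritic point tree into unbranched sections at branch
    # points and at type-code changes
    # (start sample, parent section id, attachment sample)
    stack: list[tuple[int, int, int]] = []
    for n in soma_ids:
        for k in reversed(children[n]):
            if samples[k][0] != 1:
                stack.append((k, 0, n))
    while stack:
        start, parent_sid, attach = stack.pop()
        pts: list[list[float]] = [pt(attach)]
        cur = start
        t0 = samples[start][0]
        while True:
            pts.append(pt(cur))
            kids = children[cur]
            same = [k for k in kids if samples[k][0] == t0]
            if len(kids) == 1 and len(same) == 1:
                cur = kids[0]
                continue
            break
        sec = Section(
            id=next_sid,
            parent=parent_sid,
            label=_SWC_TYPE_TO_LABEL[t0],
            points=np.asarray(pts, dtype=float),
        )
        sections.append(sec)
        this_sid = next_sid
        next_sid += 1
        for k in reversed(children[cur]):
            stack.append((k, this_sid, cur))

    return SectionTree(sections)


def write_swc(tree: SectionTree, path) -> None:
    """Write a :class:`SectionTree` back to 7-column SWC.

    Child sections attach to the parent sample whose coordinates match
    their shared first point, so geometry survives a round trip.
    """
    lines = ["# SWC export"]
    counter = [0]
    # per section: list of (xyz, emitted sample id)
    emitted: dict[int, list] = {}

    def attach_sample(sec: Section) -> int:
        target = sec.points[0, :3]
        best, best_d = -1, np.inf
        for xyz, sid in emitted[sec.parent]:
            d = float(np.linalg.norm(xyz - target))
            if d < best_d:
                best, best_d = sid, d
        return best

    for sec in tree.topological_order():
        pts = sec.points
        start = 0
        prev = -1
        if sec.parent != -1:
            prev = attach_sample(sec)
            start = 1  # first point duplicates the attachment point
        rows = []
        for i in range(start, len(pts)):
            counter[0] += 1
            n = counter[0]
            x, y, z, d = pts[i]
            lines.append(
                f"{n} {_LABEL_TO_SWC_TYPE[sec.label]} {x:.6g} {y:.6g} {z:.6g} "
                f"{d / 2.0:.6g} {prev}"
            )
            rows.append((pts[i, :3].copy(), n))
            prev = n
        emitted[sec.id] = rows
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def build_synthetic_morphology(
    soma_diam: float = 25.0,
    trunk_length: float = 500.0,
    trunk_diam: float = 10.0,
    trunk_taper: float = 0.5,
    tuft_length: float = 300.0,
    tuft_diam: float = 8.0,
    tuft_flare: float = 3.5,
    n_oblique: int = 2,
    oblique_length: float = 250.0,
    oblique_diam: float = 18.0,
    n_basal: int = 2,
    basal_length: float = 250.0,
    basal_diam: float = 14.0,
    require_bap_sites: bool = True,
) -> SectionTree:
    """Reduced CA3-like stand-in morphology: soma, tapering apical trunk with
    a flaring tuft, oblique branches, and basal dendrites.

    The apical trunk spans at least 300 µm of path distance so the dendritic
    recording sites at ~150 and ~300 µm used for back-propagating AP
    measurements exist; it tapers to ``trunk_taper`` times its proximal
    diameter and continues into a flaring "tuft" equivalent cylinder
    (diameter growing by ``tuft_flare``) that represents the collapsed
    distal branching load. Oblique branches attach near the recording sites
    and load the propagating AP the way branch points do in full arbors;
    basal dendrites attach at the soma. Dimensions follow an
    area-equivalent collapsed-arbor convention rather than anatomical
    branch-by-branch realism.
    """
    dims = [soma_diam, trunk_length, trunk_diam, oblique_length, oblique_diam,
            basal_length, basal_diam, tuft_length, tuft_diam]
    if any(d <= 0 for d in dims):
        raise ValueError("all dimensions must be positive")
    if n_oblique < 0 or n_basal < 0:
        raise ValueError("branch counts must be non-negative")
    if require_bap_sites and trunk_length < 300.0:
        raise ValueError(
            "apical trunk must span >= 300 um for the 150/300 um recording sites"
        )

    sections: list[Section] = []
    # soma: single-sample sphere encoding (equivalent cylinder L = d)
    sections.append(
        Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, soma_diam]]))
    )
    # apical trunk along +y starting at soma edge
    y0 = soma_diam / 2.0
    trunk_pts = np.array(
        [[0.0, y0, 0.0, trunk_diam],
         [0.0, y0 + trunk_length, 0.0, trunk_diam * trunk_taper]]
    )
    sections.append(Section(1, 0, "apical", trunk_pts))
    # flaring distal tuft continuing the trunk
    tuft_pts = np.array(
        [[0.0, y0 + trunk_length, 0.0, tuft_diam],
         [0.0, y0 + trunk_length + tuft_length, 0.0, tuft_diam * tuft_flare]]
    )
    sections.append(Section(2, 1, "apical", tuft_pts))
    sid = 3
    # obliques branch off the trunk near the bAP recording sites
    obl_y = [140.0, 290.0, 90.0, 390.0]
    for i in range(n_oblique):
        ya = y0 + obl_y[i % len(obl_y)]
        xdir = 1.0 if i % 2 == 0 else -1.0
        d_i = oblique_diam * (1.0 - 0.2 * i)
        pts = np.array(
            [
                [0.0, ya, 0.0, d_i],
                [xdir * oblique_length, ya, 0.0, d_i],
            ]
        )
        sections.append(Section(sid, 1, "apical", pts))
        sid += 1
    for i in range(n_basal):
        xdir = 1.0 if i % 2 == 0 else -1.0
        ang = (i // 2 + 1) * 0.5
        dx = xdir * basal_length * math.cos(ang)
        dy = -basal_length * math.sin(ang) - soma_diam / 2.0
        pts = np.array(
            [[0.0, -soma_diam / 2.0, 0.0, basal_diam], [dx, dy, 0.0, basal_diam]]
        )
        sections.append(Section(sid, 0, "basal", pts))
        sid += 1
    return SectionTree(sections)


def lambda_f(diam_um: float, f_hz: float, r_a: float, c_m: float) -> float:
    """AC length constant in µm at frequency ``f_hz``.

    ``diam_um`` in µm, ``r_a`` in Ω·cm, ``c_m`` in µF/cm². Standard cable
    result ignoring membrane resistance (valid for f >> 1/(2πτ)).
    """
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    return 1e5 * math.sqrt(diam_um / (4.0 * math.pi * f_hz * r_a * c_m))


class CompartmentalModel:
    """Discretized morphology: iso-potential compartments on a Hines-ordered tree.

    Arrays are indexed by compartment, root (soma) first and every parent
    before its children, so the branched-cable linear system can be solved
    by a single back/forward sweep. Geometry is in µm / cm², passive
    constants are ``r_m`` (kΩ·cm²), ``r_a`` (Ω·cm), ``c_m`` (µF/cm²).
    ``channel_density`` maps channel names to per-compartment maximal
    conductance (S/cm²) or permeability (cm/s) arrays.
    """

    def __init__(
        self,
        section_id: np.ndarray,
        seg_pos: np.ndarray,
        length: np.ndarray,
        diam: np.ndarray,
        parent: np.ndarray,
        path_um: np.ndarray,
        region: np.ndarray,
        r_m: float,
        r_a: float,
        c_m: float,
        d_lambda: float,
        f_lambda: float,
    ):
        self.section_id = section_id
        self.seg_pos = seg_pos
        self.length = length
        self.diam = diam
        self.parent = parent
        self.path_um = path_um
        self.region = region
        self.r_m = float(r_m)
        self.r_a = float(r_a)
        self.c_m = float(c_m)
        self.d_lambda = float(d_lambda)
        self.f_lambda = float(f_lambda)
        self.area_cm2 = (math.pi * diam * length) * 1e-8  # µm² -> cm²
        self.g_axial_uS = self._axial_conductances()
        self.channel_density: dict[str, np.ndarray] = {}

    @property
    def n_comp(self) -> int:
        return len(self.length)

    def _axial_conductances(self) -> np.ndarray:
        # half-compartment axial resistance in MΩ: 4 Ra L/2 / (π d²), µm -> cm
        r_half = (
            4.0 * self.r_a * (self.length / 2.0) / (math.pi * self.diam**2)
        ) * 1e-2
        g = np.zeros(self.n_comp)
        for i in range(1, self.n_comp):
            p = self.parent[i]
            g[i] = 1.0 / (r_half[i] + r_half[p])  # µS
        return g

    def total_area(self) -> float:
        """Total membrane area in cm²."""
        return float(self.area_cm2.sum())

    def path_distance(self, comp: int) -> float:
        """Arc-length distance from the soma centre in µm (0 on the soma)."""
        if not 0 <= comp < self.n_comp:
            raise KeyError(f"no compartment {comp}")
        return float(self.path_um[comp])

    def nearest_compartment(self, path_um: float, region: str = "apical") -> int:
        """Compartment of ``region`` nearest the requested path distance."""
        mask = self.region == region
        if not mask.any():
            raise ValueError(f"no compartments in region {region!r}")
        idx = np.flatnonzero(mask)
        return int(idx[np.argmin(np.abs(self.path_um[idx] - path_um))])

    def region_mask(self, region: str, window: tuple[float, float] | None = None):
        """Boolean mask for a region; ``window`` restricts by path distance.

        ``region='sr'`` selects the stratum radiatum: apical compartments
        within the window (default [50, 300] µm).
        """
        if region == "sr":
            lo, hi = window if window is not None else (50.0, 300.0)
            return (self.region == "apical") & (self.path_um >= lo) & (self.path_um <= hi)
        mask = self.region == region
        if window is not None:
            mask &= (self.path_um >= window[0]) & (self.path_um <= window[1])
        return mask


def _nseg(length: float, diam: float, d_lambda: float, f: float, r_a: float,
          c_m: float) -> int:
    lam = lambda_f(diam, f, r_a, c_m)
    n = max(1, math.ceil(length / (d_lambda * lam)))
    return n if n % 2 == 1 else n + 1


def discretize(
    tree: SectionTree,
    d_lambda: float = 0.1,
    f: float = 100.0,
    r_m: float = 60.0,
    r_a: float = 200.0,
    c_m: float = 0.75,
) -> CompartmentalModel:
    """Discretize a :class:`SectionTree` by the d_lambda rule.

    Each section gets the smallest odd number of equal-length segments such
    that none exceeds ``d_lambda`` times the AC length constant at ``f`` Hz.
    ``r_m`` in kΩ·cm², ``r_a`` in Ω·cm, ``c_m`` in µF/cm².
    """
    if not 0 < d_lambda <= 1:
        raise ValueError("d_lambda must be in (0, 1]")
    if f <= 0:
        raise ValueError("frequency must be positive")
    if r_m <= 0 or r_a <= 0 or c_m <= 0:
        raise ValueError("passive constants must be positive")

    order = tree.topological_order()
    sec_index = {s.id: i for i, s in enumerate(order)}

    sec_ids, seg_pos, lengths, diams, parents, paths, regions = (
        [], [], [], [], [], [], []
    )
    # per-section bookkeeping: index of last compartment, end path distance
    tail_comp: dict[int, int] = {}
    end_path: dict[int, float] = {}

    for sec in order:
        L = sec.length
        dm = sec.mean_diam()
        n = _nseg(L, dm, d_lambda, f, r_a, c_m)
        if sec.parent == -1:
            parent_comp, start_path = -1, 0.0
        else:
            parent_comp = tail_comp[sec.parent]
            start_path = end_path[sec.parent]
        # arc-length parameterization for per-segment diameters
        pts, dvals = sec.points[:, :3], sec.points[:, 3]
        if len(pts) >= 2:
            arcs = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
            )
        else:
            arcs = np.array([0.0])
        seg_len = L / n
        prev = parent_comp
        for k in range(n):
            mid = (k + 0.5) * seg_len
            d_here = dm if len(pts) < 2 else float(np.interp(mid, arcs, dvals))
            sec_ids.append(sec.id)
            seg_pos.append((k + 0.5) / n)
            lengths.append(seg_len)
            diams.append(d_here)
            parents.append(prev)
            if sec.label == "soma":
                paths.append(0.0)
            else:
                paths.append(start_path + mid)
            regions.append(sec.label)
            prev = len(lengths) - 1
        tail_comp[sec.id] = prev
        end_path[sec.id] = 0.0 if sec.label == "soma" else start_path + L

    return CompartmentalModel(
        section_id=np.asarray(sec_ids),
        seg_pos=np.asarray(seg_pos),
        length=np.asarray(lengths),
        diam=np.asarray(diams),
        parent=np.asarray(parents, dtype=np.int64),
        path_um=np.asarray(paths),
        region=np.asarray(regions, dtype=object),
        r_m=r_m,
        r_a=r_a,
        c_m=c_m,
        d_lambda=d_lambda,
        f_lambda=f,
    )
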