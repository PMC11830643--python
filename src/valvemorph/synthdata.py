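"""Synthetic inputs with known ground truth.

Every stage of the pipeline can be exercised without external data:

* **Parametric valves** — a valve is modelled as the shell of material
  between two nested hemi-ellipsoids (outer semi-axes ``a, b, c``; inner
  ``a - t, b - t, c - t`` for wall thickness ``t``), closed by an annular
  face in the commissural plane ``z = 0``.  Its volumes are analytic
  (hemi-ellipsoid volume ``2/3 pi abc``), so the proportional shell volume
  is known exactly: ``pSV = (abc - a'b'c') / abc``.  The proxy captures the
  quantities the morphometric variables actually use — enclosed volumes and
  bounding boxes — without modelling coiling, ornament or hinge.
* **Birth–death trees** — Gillespie simulation from a single lineage,
  stopped the moment the requested number of extant tips is reached
  (extinct side-branches pruned, runs where the clade dies out retried).
* **Brownian traits** — independent normal increments with variance
  ``sigma2 x branch length`` summed root to tip.
* **Cohorts** — a four-family, two-clade specimen table plus matching tree
  emulating the study system: three asiphonate archiheterodont families
  (Astartidae, Carditidae, Crassatellidae) with high proportional shell
  volume and broad shell-length variance, and the siphonate Veneridae with
  low pSV, larger but tightly packed shell lengths, and the full spread of
  substratum-use groups.  Traits can be drawn independently or as Brownian
  motion with family mean shifts (strong phylogenetic signal).

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mesh_io import INTERIOR_SURFACE, SHELL_SOLID, ValveMesh, signed_volume
from .traits import SpecimenRecord, classify_all

__all__ = [
    "ShellParams",
    "FamilySpec",
    "CohortConfig",
    "Cohort",
    "make_valve",
    "simulate_tree",
    "simulate_bm",
    "make_cohort",
    "default_cohort_config",
]

DEFAULT_SUBDIVISION = 4


# ---------------------------------------------------------------------------
# parametric valves


@dataclass(frozen=True)
class ShellParams:
    """Nested hemi-ellipsoid valve: outer semi-axes and wall thickness (mm).

    ``subdivision`` controls mesh resolution: the hemisphere is meshed with
    ``4 * 2**subdivision`` latitude rings (and twice as many longitude
    segments), so linear resolution doubles per level.  By default the
    inner surface sits a uniform wall thickness inside the outer one;
    arbitrary inner semi-axes can be given instead via ``inner``.
    """

    a: float
    b: float
    c: float
    thickness: float = 0.0
    subdivision: int = DEFAULT_SUBDIVISION
    inner: "tuple | None" = None

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.inner is None:
            if not 0 < self.thickness < min(self.a, self.b, self.c):
                raise ValueError("thickness must lie in (0, min(a, b, c))")
        else:
            ai, bi, ci = self.inner
            if not (0 < ai < self.a and 0 < bi < self.b and 0 < ci < self.c):
                raise ValueError("inner semi-axes must nest inside the outer")
        if self.subdivision < 1:
            raise ValueError("subdivision must be >= 1")

    @property
    def inner_axes(self) -> tuple:
        if self.inner is not None:
            return tuple(self.inner)
        t = self.thickness
        return (self.a - t, self.b - t, self.c - t)

    @property
    def analytic_valve_shell_volume(self) -> float:
        ai, bi, ci = self.inner_axes
        return (2.0 * math.pi / 3.0) * (self.a * self.b * self.c - ai * bi * ci)

    @property
    def analytic_valve_internal_volume(self) -> float:
        ai, bi, ci = self.inner_axes
        return (2.0 * math.pi / 3.0) * (ai * bi * ci)

    @property
    def analytic_pSV(self) -> float:
        ai, bi, ci = self.inner_axes
        abc = self.a * self.b * self.c
        return (abc - ai * bi * ci) / abc


def _hemi_grid(a: float, b: float, c: float, n_rings: int, n_seg: int):
    """Vertices of a z >= 0 hemi-ellipsoid: pole then rings of n_seg points,
    the last ring lying in the plane z = 0."""
    verts = [(0.0, 0.0, c)]
    for i in range(1, n_rings + 1):
        theta = (math.pi / 2.0) * i / n_rings
        st, ct = math.sin(theta), math.cos(theta)
        for j in range(n_seg):
            phi = 2.0 * math.pi * j / n_seg
            verts.append((a * st * math.cos(phi), b * st * math.sin(phi),
                          c * ct))
    return np.asarray(verts)


def _hemi_faces(n_rings: int, n_seg: int, offset: int = 0) -> np.ndarray:
    """Triangulation of :func:`_hemi_grid` with outward (away from the
    ellipsoid centre) normals."""
    faces = []
    ring = lambda i, j: offset + 1 + (i - 1) * n_seg + (j % n_seg)  # noqa: E731
    for j in range(n_seg):
        faces.append([offset, ring(1, j), ring(1, j + 1)])
    for i in range(1, n_rings):
        for j in range(n_seg):
            faces.append([ring(i, j), ring(i + 1, j), ring(i + 1, j + 1)])
            faces.append([ring(i, j), ring(i + 1, j + 1), ring(i, j + 1)])
    return np.asarray(faces, dtype=np.int64)


def make_valve(params: ShellParams) -> tuple:
    """Build ``(shell_solid, interior)`` meshes for a parametric valve.

    The shell solid is the closed surface bounding the material between the
    outer and inner hemi-ellipsoids, including the flat annulus at the
    commissural plane; the interior is the open inner hemi-ellipsoid
    surface with its single boundary loop at ``z = 0``.  Both are
    watertight/manifold by construction (equator rings are shared).
    """
    n_rings = 4 * 2 ** params.subdivision
    n_seg = 2 * n_rings
    if n_seg < 3:
        raise ValueError("subdivision too low to close the annulus")
    ai, bi, ci = params.inner_axes

    outer_v = _hemi_grid(params.a, params.b, params.c, n_rings, n_seg)
    inner_v = _hemi_grid(ai, bi, ci, n_rings, n_seg)
    inner_offset = len(outer_v)
    outer_f = _hemi_faces(n_rings, n_seg)
    # inner wall: outward-from-solid normals point toward the cavity centre
    inner_f = _hemi_faces(n_rings, n_seg, offset=inner_offset)[:, ::-1]

    # annulus in z = 0 joining the two equator rings; outward normal is -z
    outer_eq = 1 + (n_rings - 1) * n_seg
    inner_eq = inner_offset + 1 + (n_rings - 1) * n_seg
    annulus = []
    for j in range(n_seg):
        jn = (j + 1) % n_seg
        o0, o1 = outer_eq + j, outer_eq + jn
        i0, i1 = inner_eq + j, inner_eq + jn
        annulus.append([o0, i0, i1])
        annulus.append([o0, i1, o1])
    annulus = np.asarray(annulus, dtype=np.int64)

    vertices = np.vstack([outer_v, inner_v])
    faces = np.vstack([outer_f, inner_f, annulus])
    shell = ValveMesh(vertices, faces, role=SHELL_SOLID)
    if signed_volume(shell) < 0:
        shell = ValveMesh(vertices, faces[:, ::-1], role=SHELL_SOLID)

    interior = ValveMesh(inner_v, _hemi_faces(n_rings, n_seg),
                         role=INTERIOR_SURFACE)
    return shell, interior


# ---------------------------------------------------------------------------
# trees and Brownian traits


def simulate_tree(n_tips: int, birth: float, death: float = 0.0,
                  seed: int = 0, max_retries: int = 1000,
                  label_format: str = "T{:03d}") -> dendropy.Tree:
    """Birth–death tree conditioned on the number of extant tips.

    Gillespie simulation from a single lineage; once the ``n_tips``-th
    extant lineage appears the clock runs on to just before the next event
    (so terminal branches are strictly positive), extinct side branches are
    pruned, and runs where the clade dies out are retried (up to
    ``max_retries``).  The returned tree starts at the root split (no stem)
    and is ultrametric.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not birth > death >= 0:
        raise ValueError("require birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        result = _bd_attempt(n_tips, birth, death, rng)
        if result is not None:
            newick = result
            return dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
    raise RuntimeError(f"all lineages went extinct in {max_retries} attempts")


def _bd_attempt(n_tips, birth, death, rng):
    # node records: [parent, birth_time, death_time or None, is_tip]
    parent = {0: None}
    t_birth = {0: 0.0}
    t_end = {}
    children = {}
    alive = [0]
    next_id = 1
    t = 0.0
    total_rate = birth + death
    while 0 < len(alive) < n_tips:
        t += rng.exponential(1.0 / (total_rate * len(alive)))
        lineage = alive[rng.integers(len(alive))]
        if rng.random() < birth / total_rate:
            kids = (next_id, next_id + 1)
            next_id += 2
            for k in kids:
                parent[k] = lineage
                t_birth[k] = t
            children[lineage] = kids
            t_end[lineage] = t
            alive.remove(lineage)
            alive.extend(kids)
        else:
            t_end[lineage] = t
            alive.remove(lineage)
    if not alive:
        return None
    # run the clock to just before the next event so the tree has exactly
    # n extant tips and strictly positive terminal branches
    t += rng.exponential(1.0 / (total_rate * len(alive)))
    for lineage in alive:
        t_end[lineage] = t

    extant = set(alive)

    # Reconstruct the extant-only tree by iterative postorder.  Each entry
    # is (newick_text, time_of_subtree_root): a tip's time is the present,
    # an internal node's its split time.  Nodes whose subtree is extinct
    # drop out; nodes with one surviving side pass their child through,
    # which accumulates branch length across the suppressed unifurcation.
    out = {}
    counter = 0
    stack = [(0, False)]
    while stack:
        nid, processed = stack.pop()
        if not processed:
            stack.append((nid, True))
            stack.extend((kid, False) for kid in children.get(nid, ()))
            continue
        if nid in extant:
            counter += 1
            out[nid] = (f"T{counter:03d}", t_end[nid])
        elif nid in children:
            kids = [out[k] for k in children[nid] if out[k] is not None]
            if not kids:
                out[nid] = None
            elif len(kids) == 1:
                out[nid] = kids[0]
            else:
                split = t_end[nid]
                parts = [f"{text}:{tm - split:.10f}" for text, tm in kids]
                out[nid] = (f"({','.join(parts)})", split)
        else:
            out[nid] = None

    text, _ = out[0]
    return text + ";"


def simulate_bm(tree: dendropy.Tree, sigma2: float = 1.0,
                root_value: float = 0.0, seed: int = 0) -> pd.Series:
    """Brownian-motion tip values: per-branch normal increments with
    variance ``sigma2 x branch length``, accumulated root to tip."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    value = {tree.seed_node: float(root_value)}
    tips = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            bl = node.edge.length or 0.0
            step = rng.normal(0.0, math.sqrt(sigma2 * bl)) if sigma2 > 0 else 0.0
            value[node] = value[node.parent_node] + step
        if node.is_leaf():
            tips[node.taxon.label] = value[node]
    return pd.Series(tips, name="trait")


# ---------------------------------------------------------------------------
# cohorts


def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class FamilySpec:
    """Per-family generating parameters (pSV on the logit scale)."""

    n: int
    psv_logit_mean: float
    psv_logit_sd: float
    logsl_mean: float       # log10 mm
    logsl_sd: float
    xs_mean: float
    xs_sd: float
    crown_height: float     # Myr
    n_epifaunal: int = 0
    n_borer: int = 0
    n_nestler: int = 0


@dataclass(frozen=True)
class CohortConfig:
    families: dict
    birth: float = 0.08      # per Myr
    death: float = 0.03
    trait_mode: str = "brownian-with-family-shifts"
    seed: int = 0
    sinus_fraction_range: tuple = (0.1, 0.8)

    def __post_init__(self):
        for name, spec in self.families.items():
            if spec.psv_logit_sd <= 0 or spec.logsl_sd <= 0 or spec.xs_sd <= 0:
                raise ValueError(f"{name}: all sds must be > 0")
        if self.trait_mode not in ("independent",
                                   "brownian-with-family-shifts"):
            raise ValueError(f"unknown trait mode {self.trait_mode!r}")

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.families.values())


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Study-structured defaults: family sample sizes 12/72/40/126, high
    archiheterodont pSV, low but broad venerid pSV, venerid shell lengths
    larger yet least variable, XS near 1, a few epifaunal carditids, and
    borer/nestler venerids."""
    return CohortConfig(
        families={
            "Astartidae": FamilySpec(
                n=12, psv_logit_mean=_logit(0.35), psv_logit_sd=0.30,
                logsl_mean=1.30, logsl_sd=0.25, xs_mean=0.95, xs_sd=0.08,
                crown_height=100.0),
            "Carditidae": FamilySpec(
                n=72, psv_logit_mean=_logit(0.30), psv_logit_sd=0.35,
                logsl_mean=1.35, logsl_sd=0.30, xs_mean=1.05, xs_sd=0.15,
                crown_height=120.0, n_epifaunal=6),
            "Crassatellidae": FamilySpec(
                n=40, psv_logit_mean=_logit(0.40), psv_logit_sd=0.30,
                logsl_mean=1.40, logsl_sd=0.35, xs_mean=0.95, xs_sd=0.08,
                crown_height=120.0),
            "Veneridae": FamilySpec(
                n=126, psv_logit_mean=_logit(0.15), psv_logit_sd=0.60,
                logsl_mean=1.60, logsl_sd=0.15, xs_mean=1.00, xs_sd=0.10,
                crown_height=140.0, n_borer=4, n_nestler=4),
        },
        seed=seed)


#: Node depths (Myr from the root, tips at 200) of the fixed backbone
#: ((Astartidae, (Carditidae, Crassatellidae)), Veneridae).
_BACKBONE_DEPTH = {"root": 0.0, "archi": 30.0, "cardi_crass": 60.0}
_TREE_HEIGHT = 200.0


def _family_subtree(name: str, spec: FamilySpec, birth, death, seed,
                    prefix: str) -> str:
    """Newick (no trailing semicolon) of a family crown group scaled to the
    family's crown height, with tips relabelled ``<prefix>_sNN``."""
    tree = simulate_tree(spec.n, birth, death, seed=seed)
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    scale = spec.crown_height / max(depths)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * scale
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"{prefix}_s{i:03d}"
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip().rstrip(";")


def build_cohort_tree(config: CohortConfig, seeds: dict) -> dendropy.Tree:
    """Two-clade backbone with one simulated crown group per family."""
    sub = {name: _family_subtree(name, spec, config.birth, config.death,
                                 seeds[name], prefix=name[:4])
           for name, spec in config.families.items()}
    d = _BACKBONE_DEPTH
    h = _TREE_HEIGHT
    stem = {name: (h - config.families[name].crown_height) -
            (d["archi"] if name == "Astartidae"
             else d["cardi_crass"] if name in ("Carditidae", "Crassatellidae")
             else d["root"])
            for name in config.families}
    cc = (f"({sub['Carditidae']}:{stem['Carditidae']},"
          f"{sub['Crassatellidae']}:{stem['Crassatellidae']})"
          f":{d['cardi_crass'] - d['archi']}")
    archi = (f"({sub['Astartidae']}:{stem['Astartidae']},{cc})"
             f":{d['archi'] - d['root']}")
    newick = f"({archi},{sub['Veneridae']}:{stem['Veneridae']});"
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def _family_traits(config: CohortConfig, tree, taxa_by_family, seeds):
    """Draw (psv, logsl, xs) per taxon, either iid or as Brownian motion
    with family-level shifts (deviations standardized within family to the
    configured sd — a linear map, so phylogenetic signal is preserved)."""
    rng = np.random.default_rng(seeds["traits"])
    traits = {}
    if config.trait_mode == "independent":
        for name, spec in config.families.items():
            m = len(taxa_by_family[name])
            psv = _expit(rng.normal(spec.psv_logit_mean, spec.psv_logit_sd, m))
            logsl = rng.normal(spec.logsl_mean, spec.logsl_sd, m)
            xs = np.abs(rng.normal(spec.xs_mean, spec.xs_sd, m))
            for i, taxon in enumerate(taxa_by_family[name]):
                traits[taxon] = (psv[i], logsl[i], xs[i])
        return traits

    for k, trait_name in enumerate(("psv", "logsl", "xs")):
        bm = simulate_bm(tree, sigma2=1.0, seed=seeds["traits"] + 17 * (k + 1))
        for name, spec in config.families.items():
            taxa = taxa_by_family[name]
            dev = bm[taxa].to_numpy()
            dev = (dev - dev.mean()) / (dev.std(ddof=1) or 1.0)
            if trait_name == "psv":
                vals = _expit(spec.psv_logit_mean + spec.psv_logit_sd * dev)
            elif trait_name == "logsl":
                vals = spec.logsl_mean + spec.logsl_sd * dev
            else:
                vals = np.abs(spec.xs_mean + spec.xs_sd * dev)
            for taxon, v in zip(taxa, vals):
                traits.setdefault(taxon, [None, None, None])[k] = float(v)
    return {t: tuple(v) for t, v in traits.items()}


@dataclass
class Cohort:
    """A generated study system: specimen records, tree, optional meshes."""

    records: list
    tree: dendropy.Tree
    config: CohortConfig
    meshes: dict = field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        from .traits import records_to_frame

        return records_to_frame(self.records)


def thickness_for_psv(a: float, b: float, c: float, psv: float) -> float:
    """Wall thickness making a nested hemi-ellipsoid valve's analytic pSV
    equal the target."""
    lo, hi = 1e-9 * min(a, b, c), min(a, b, c) * (1 - 1e-9)

    def f(t):
        return ((a * b * c - (a - t) * (b - t) * (c - t)) / (a * b * c)
                - psv)

    return brentq(f, lo, hi)


def make_cohort(config: "CohortConfig | None" = None, seed: "int | None" = None,
                emit_meshes: bool = False,
                mesh_subdivision: int = DEFAULT_SUBDIVISION) -> Cohort:
    """Generate a full synthetic study system.

    Species names, family membership, siphonate condition, habit
    annotations and sinus fractions are assigned; pSV / logSL / XS are
    drawn per the config; substratum categories come from the actual
    classification rules, never assigned directly.  With ``emit_meshes``
    every specimen also gets a parametric valve whose analytic metrics
    match its drawn values.  Deterministic for a given config.
    """
    if config is None:
        config = default_cohort_config(seed=0 if seed is None else seed)
    elif seed is not None:
        raise ValueError("pass the seed inside the config or alone, not both")
    ss = np.random.SeedSequence(config.seed)
    child = ss.generate_state(len(config.families) + 2)
    seeds = {name: int(s % (2 ** 31)) for name, s in
             zip(config.families, child)}
    seeds["traits"] = int(child[-2] % (2 ** 31))
    seeds["assign"] = int(child[-1] % (2 ** 31))

    tree = build_cohort_tree(config, seeds)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    taxa_by_family = {name: [t for t in labels if t.startswith(name[:4] + "_")]
                      for name in config.families}
    traits = _family_traits(config, tree, taxa_by_family, seeds)

    rng = np.random.default_rng(seeds["assign"])
    records = []
    for name, spec in config.families.items():
        taxa = taxa_by_family[name]
        siphonate = name == "Veneridae"
        habits = [None] * len(taxa)
        special = (["epifaunal"] * spec.n_epifaunal
                   + ["borer"] * spec.n_borer + ["nestler"] * spec.n_nestler)
        for slot, habit in zip(rng.choice(len(taxa), size=len(special),
                                          replace=False), special):
            habits[slot] = habit
        for taxon, habit in zip(taxa, habits):
            psv, logsl, xs = traits[taxon]
            sl = 10.0 ** logsl
            sinus = None
            if siphonate:
                lo, hi = config.sinus_fraction_range
                sinus = float(rng.uniform(lo, hi))
            records.append(SpecimenRecord(
                taxon=taxon, family=name, siphonate=siphonate,
                habit_annotation=habit, sinus_depth_fraction=sinus,
                metrics={"pSV": float(psv), "SL": float(sl),
                         "logSL": float(logsl), "XS": float(xs)}))
    classify_all(records)

    meshes = {}
    if emit_meshes:
        for rec in records:
            sl = rec.metrics["SL"]
            xs = rec.metrics["XS"]
            psv = rec.metrics["pSV"]
            a = sl / 2.0
            b = a / 1.25          # fixed length:height proportion
            c = xs * b            # width = 2c, height = 2b -> XS = c/b
            t = thickness_for_psv(a, b, c, psv)
            params = ShellParams(a=a, b=b, c=c, thickness=t,
                                 subdivision=mesh_subdivision)
            meshes[rec.taxon] = make_valve(params)
    return Cohort(records=records, tree=tree, config=config, meshes=meshes)
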