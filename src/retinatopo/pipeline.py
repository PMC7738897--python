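"""Study-level orchestration: regions, VOIs, group statistics, full runs.

The study design mirrors a normoxia-versus-OIR comparison on n = 5 retinas
per group.  Each retina is partitioned into central / middle / peripheral
regions by normalised distance from the optic-disk axis (equal radial thirds
by default), morphometrics are sampled in randomly placed volumes of
interest (VOIs, 200 µm thick by default), topology is computed on the whole
traced network, and the vertical-sprout volume fraction comes from the PCA
sliding-window segmentation of the voxelised stack.  Two-group comparisons
use the unpaired two-tailed Student's t-test (pooled variance; Welch by
flag), multi-group comparisons one-way ANOVA with Tukey post hoc; p < 0.05
is called significant.

Between-animal variability: real littermates differ far more than lattice
seed noise allows, dominating the variance of dimensionless local metrics
such as the mean clustering coefficient.  ``run_study`` therefore draws
per-sample lognormal factors for ``chord_rate`` (CV 0.4) and
``sprout_density`` (CV 0.15), emulating inter-animal spread while leaving
each single retina's generator contract untouched.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .graph import VascularGraph, compute_morphometrics
from .segmentation import SegmentationParams, segment_sprouts
from .synthetic import (
    OirParams,
    RetinaParams,
    SyntheticRetina,
    apply_oir,
    generate_retina,
    voxelize,
)
from .topology import clustering_summary
from .volume import PLEXUS, SPROUT

REGIONS = ("central", "middle", "peripheral")
P_SIGNIFICANT = 0.05


class ConfigError(ValueError):
    """Unknown or invalid study-configuration keys."""


class InsufficientDataError(ValueError):
    """A statistical comparison was requested with fewer than 2 observations."""


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class RegionSpec:
    """Central / middle / peripheral partition around the optic-disk axis."""

    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    max_radius_um: float | None = None

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not 0.0 < b1 < b2 < 1.0:
            raise ValueError("need 0 < b1 < b2 < 1")
        if np.linalg.norm(self.axis) == 0:
            raise ValueError("zero-length axis")


def radial_fraction(points: np.ndarray, spec: RegionSpec,
                    max_radius_um: float | None = None) -> np.ndarray:
    """Normalised distance from the optic-disk axis for world points (n, 3)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(spec.origin_um)
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    along = pts @ axis
    perp = pts - along[:, None] * axis[None, :]
    r = np.linalg.norm(perp, axis=1)
    r_max = max_radius_um or spec.max_radius_um
    if r_max is None:
        r_max = float(r.max()) or 1.0
    return r / r_max


def partition_regions(points: np.ndarray, spec: RegionSpec,
                      max_radius_um: float | None = None) -> np.ndarray:
    """Region name per point; boundaries are half-open ``[lo, hi)``."""
    frac = radial_fraction(points, spec, max_radius_um)
    b1, b2 = spec.boundaries
    out = np.full(len(frac), "peripheral", dtype=object)
    out[frac < b2] = "middle"
    out[frac < b1] = "central"
    return out


# ---------------------------------------------------------------------------
# VOIs
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class VOI:
    """An oriented box: rows of ``axes`` are unit vectors (u, v, thickness)."""

    center_um: np.ndarray
    axes: np.ndarray  # (3, 3)
    half_extents_um: np.ndarray  # (3,)
    region: str = ""

    def local(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center_um
        return pts @ self.axes.T

    def contains(self, points: np.ndarray) -> np.ndarray:
        loc = self.local(points)
        return (np.abs(loc) <= self.half_extents_um + 1e-9).all(axis=1)

    @property
    def thickness_um(self) -> float:
        return 2.0 * float(self.half_extents_um[2])


def _local_frame(radial: np.ndarray) -> np.ndarray:
    w = radial / np.linalg.norm(radial)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(w @ helper) > 0.99:
        helper = np.array([1.0, 0.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w])


def sample_vois(
    retina: SyntheticRetina,
    region: str,
    spec: RegionSpec | None = None,
    n: int = 5,
    thickness_um: float = 200.0,
    footprint_um: float | None = 250.0,
    seed: int = 0,
) -> list[VOI]:
    """``n`` boxes of the stated thickness uniformly placed within a region.

    Thickness runs along the local depth axis: the local radial direction in
    hemisphere mode, +z in flat mode (where boxes are axis-aligned).
    Deterministic per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    params = retina.params
    spec = spec or RegionSpec(max_radius_um=params.shell_radius_um)
    r_shell = params.shell_radius_um
    if thickness_um <= 0 or thickness_um > 2 * r_shell:
        raise ValueError("VOI thickness does not fit the sample extent")
    b1, b2 = spec.boundaries
    lo, hi = {"central": (0.0, b1), "middle": (b1, b2), "peripheral": (b2, 1.0)}[region]

    rng = np.random.default_rng(seed)
    half_lat = (2.0 * r_shell) if footprint_um is None else footprint_um / 2.0
    half = np.array([half_lat, half_lat, thickness_um / 2.0])
    mid_depth = r_shell - params.layer_separation_um / 2.0
    vois = []
    for _ in range(n):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        if params.geometry_mode == "hemisphere":
            # uniform per shell area within the annulus: cos(polar) uniform
            c_lo, c_hi = math.asin(lo), math.asin(min(hi, 1.0 - 1e-12))
            u = rng.uniform(math.cos(c_hi), math.cos(c_lo))
            c = math.acos(u)
            direction = np.array(
                [math.sin(c) * math.cos(phi), math.sin(c) * math.sin(phi), math.cos(c)]
            )
            center = np.asarray(spec.origin_um) + mid_depth * direction
            axes = _local_frame(direction)
        else:
            f = math.sqrt(rng.uniform(lo * lo, hi * hi))
            center = np.asarray(spec.origin_um) + np.array(
                [f * r_shell * math.cos(phi), f * r_shell * math.sin(phi),
                 params.layer_separation_um / 2.0]
            )
            axes = np.eye(3)
        vois.append(VOI(center_um=center, axes=axes, half_extents_um=half.copy(),
                        region=region))
    return vois


def _clip_length(p0: np.ndarray, p1: np.ndarray, voi: VOI) -> float:
    """Length of the segment portion inside the box (slab clipping)."""
    a, b = voi.local(np.stack([p0, p1]))
    d = b - a
    t0, t1 = 0.0, 1.0
    for k in range(3):
        h = voi.half_extents_um[k]
        if abs(d[k]) < 1e-12:
            if abs(a[k]) > h:
                return 0.0
            continue
        lo = (-h - a[k]) / d[k]
        hi = (h - a[k]) / d[k]
        if lo > hi:
            lo, hi = hi, lo
        t0, t1 = max(t0, lo), min(t1, hi)
        if t0 >= t1:
            return 0.0
    return float((t1 - t0) * np.linalg.norm(p1 - p0))


def voi_morphometrics(graph: VascularGraph, voi: VOI) -> dict[str, float]:
    """Clipped length/volume plus node counts and connectivity within a VOI."""
    total_length = 0.0
    total_volume = 0.0
    for edge in graph.edges:
        seg_len = sum(
            _clip_length(p0, p1, voi)
            for p0, p1 in zip(edge.polyline[:-1], edge.polyline[1:])
        )
        total_length += seg_len
        total_volume += math.pi * edge.radius**2 * seg_len
    if graph.n_nodes:
        ids = graph.node_ids()
        inside = voi.contains(np.array([graph.nodes[i].position for i in ids]))
        inner_ids = [i for i, flag in zip(ids, inside) if flag]
    else:
        inner_ids = []
    deg = graph.degrees()
    sub = graph.subgraph(inner_ids)
    chi = sub.n_nodes - sub.n_edges
    return {
        "total_length": total_length,
        "total_volume": total_volume,
        "branch_points": float(sum(1 for i in inner_ids if deg[i] >= 3)),
        "n_nodes": float(len(inner_ids)),
        "connectivity": float(1 - chi),
    }


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroupComparison:
    metric: str
    test: str  # t_test_two_tailed | anova_tukey
    groups: dict[str, dict]  # name -> {mean, sd, n}
    statistic: float
    p_value: float
    significant: bool
    tukey: list[dict] | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compare_groups(
    groups: dict[str, np.ndarray], metric: str = "", welch: bool = False
) -> GroupComparison:
    """Two groups → unpaired two-tailed t-test; ≥3 → one-way ANOVA + Tukey."""
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 observations")
    summary = {
        k: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(len(v))}
        for k, v in arrays.items()
    }
    values = list(arrays.values())
    tukey_rows = None
    if len(values) == 2:
        res = stats.ttest_ind(values[0], values[1], equal_var=not welch)
        test = "t_test_two_tailed"
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.f_oneway(*values)
        statistic, p = float(res.statistic), float(res.pvalue)
        test = "anova_tukey"
        tk = stats.tukey_hsd(*values)
        names = list(arrays)
        tukey_rows = []
        for i in range(len(values)):
            for j in range(i + 1, len(values)):
                tukey_rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "statistic": float(tk.statistic[i, j]),
                        "p_value": float(tk.pvalue[i, j]),
                    }
                )
    if math.isnan(p):  # identical constant groups
        statistic, p = 0.0, 1.0
    return GroupComparison(
        metric=metric,
        test=test,
        groups=summary,
        statistic=statistic,
        p_value=p,
        significant=bool(p < P_SIGNIFICANT),
        tukey=tukey_rows,
    )


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------

_RETINA_KEYS = {f.name for f in dataclasses.fields(RetinaParams)} - {"seed"}
_OIR_KEYS = {f.name for f in dataclasses.fields(OirParams)} - {"seed"}
_SEG_KEYS = {f.name for f in dataclasses.fields(SegmentationParams)}


@dataclasses.dataclass
class StudyConfig:
    master_seed: int = 0
    n_per_group: int = 5
    retina: dict = dataclasses.field(default_factory=dict)
    oir: dict = dataclasses.field(default_factory=dict)
    segmentation: dict = dataclasses.field(default_factory=dict)
    voxel_size_um: float = 4.0
    segment: bool = True  # run the PCA segmentation per sample
    n_vois: int = 5
    voi_thickness_um: float = 200.0
    voi_footprint_um: float = 250.0
    chord_rate_cv: float = 0.4
    sprout_density_cv: float = 0.15
    boundaries: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)

    def __post_init__(self) -> None:
        bad = set(self.retina) - _RETINA_KEYS
        bad |= {f"oir.{k}" for k in set(self.oir) - _OIR_KEYS}
        bad |= {f"segmentation.{k}" for k in set(self.segmentation) - _SEG_KEYS}
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")

    @classmethod
    def from_dict(cls, payload: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = dict(payload)
        if "boundaries" in cfg:
            cfg["boundaries"] = tuple(cfg["boundaries"])
        return cls(**cfg)


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    if cv <= 0:
        return 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return float(rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma))


@dataclasses.dataclass
class StudyReport:
    rows: pd.DataFrame  # tidy: sample, group, region, metric, value
    comparisons: dict[str, GroupComparison]
    regional_anova: dict[str, GroupComparison]
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "comparisons": {k: v.as_dict() for k, v in sorted(self.comparisons.items())},
            "regional_anova": {
                k: v.as_dict() for k, v in sorted(self.regional_anova.items())
            },
            "rows": self.rows.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1, default=float)

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "report.csv", index=False)
        (out / "report.json").write_text(self.to_json())


def _sample_metrics(
    retina: SyntheticRetina,
    config: StudyConfig,
    spec: RegionSpec,
    voi_seed: int,
) -> dict[str, float]:
    graph = retina.graph
    morpho = compute_morphometrics(graph)
    topo = clustering_summary(graph)
    metrics: dict[str, float] = {
        "total_length": morpho.total_length,
        "total_volume": morpho.total_volume,
        "branch_points": float(morpho.branch_points),
        "n_nodes": float(morpho.n_nodes),
        "connectivity": float(topo.connectivity),
        "mean_clustering": topo.mean_clustering,
        "zero_fraction": topo.zero_fraction,
    }
    if config.segment and graph.n_edges:
        vol, _truth = voxelize(graph, config.voxel_size_um)
        seg_params = SegmentationParams(**config.segmentation)
        labels, _ = segment_sprouts(vol, seg_params)
        fg = labels.foreground_indices()
        if len(fg):
            lab = labels.data[tuple(fg.T)]
            centers = labels.voxel_centers(fg)
            regions = partition_regions(
                centers, spec, max_radius_um=retina.params.shell_radius_um
            )
            fore = lab != 0
            metrics["sprout_fraction"] = float(
                (lab == SPROUT).sum() / max(fore.sum(), 1)
            )
            for region in ("middle", "peripheral"):
                m = (regions == region) & fore
                if m.sum():
                    metrics[f"sprout_fraction_{region}"] = float(
                        (lab[m] == SPROUT).sum() / m.sum()
                    )
    # regional VOI morphometrics
    for r_i, region in enumerate(REGIONS):
        vois = sample_vois(
            retina,
            region,
            spec,
            n=config.n_vois,
            thickness_um=config.voi_thickness_um,
            footprint_um=config.voi_footprint_um,
            seed=voi_seed + r_i,
        )
        for v_i, voi in enumerate(vois):
            rec = voi_morphometrics(graph, voi)
            for key, value in rec.items():
                metrics[f"voi/{region}/{v_i}/{key}"] = value
    return metrics


def run_study(config: StudyConfig | dict, out_dir: str | Path | None = None) -> StudyReport:
    """Generate both cohorts, quantify each sample, and compare the groups."""
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    base_retina = RetinaParams(**config.retina)
    base_oir = OirParams(**config.oir)
    spec = RegionSpec(
        boundaries=config.boundaries, max_radius_um=base_retina.shell_radius_um
    )

    # paired design: OIR sample i is the perturbed twin of normoxia sample i,
    # so a zero-probability perturbation yields literally identical cohorts
    ss = np.random.SeedSequence(config.master_seed)
    state = ss.generate_state(4 * config.n_per_group) & 0x7FFFFFFF

    rows = []
    sample_seeds: dict[str, int] = {}
    per_group: dict[str, list[dict[str, float]]] = {"normoxia": [], "oir": []}
    for i in range(config.n_per_group):
        gen_seed, oir_seed, het_seed, voi_seed = (
            int(v) for v in state[4 * i : 4 * i + 4]
        )
        het = np.random.default_rng(het_seed)
        params = dataclasses.replace(
            base_retina,
            seed=gen_seed,
            chord_rate=min(
                base_retina.chord_rate * _lognormal_factor(het, config.chord_rate_cv),
                1.0,
            ),
            sprout_density=min(
                base_retina.sprout_density
                * _lognormal_factor(het, config.sprout_density_cv),
                1.0,
            ),
        )
        healthy = generate_retina(params)
        perturbed = apply_oir(healthy, dataclasses.replace(base_oir, seed=oir_seed))
        for group, retina in (("normoxia", healthy), ("oir", perturbed)):
            sample = f"{group}_{i + 1}"
            sample_seeds[sample] = gen_seed
            metrics = _sample_metrics(retina, config, spec, voi_seed)
            per_group[group].append(metrics)
            for key, value in metrics.items():
                region = key.split("/")[1] if key.startswith("voi/") else "whole"
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "region": region,
                        "metric": key,
                        "value": value,
                    }
                )

    rows_df = pd.DataFrame(rows)

    group_metrics = [
        "total_length",
        "total_volume",
        "branch_points",
        "connectivity",
        "mean_clustering",
    ]
    if config.segment:
        group_metrics += [
            "sprout_fraction",
            "sprout_fraction_middle",
            "sprout_fraction_peripheral",
        ]
    comparisons: dict[str, GroupComparison] = {}
    for metric in group_metrics:
        series = {
            g: np.array([m[metric] for m in per_group[g] if metric in m])
            for g in per_group
        }
        if min(len(v) for v in series.values()) >= 2:
            comparisons[metric] = compare_groups(series, metric=metric)

    # normoxia regional homogeneity (ANOVA + Tukey across regions); the study
    # design is n = n_per_group VOIs per region — one VOI per animal — so the
    # test sees VOI-level variability rather than a pooled-sample average
    regional: dict[str, GroupComparison] = {}
    for metric in ("total_length", "total_volume", "branch_points", "connectivity"):
        by_region = {
            region: np.array(
                [m[f"voi/{region}/0/{metric}"] for m in per_group["normoxia"]]
            )
            for region in REGIONS
        }
        regional[metric] = compare_groups(by_region, metric=f"regional_{metric}")

    provenance = {
        "version": __version__,
        "master_seed": config.master_seed,
        "n_per_group": config.n_per_group,
        "retina_params": dataclasses.asdict(base_retina),
        "oir_params": dataclasses.asdict(base_oir),
        "config": dataclasses.asdict(config),
        "sample_seeds": sample_seeds,
    }
    report = StudyReport(
        rows=rows_df,
        comparisons=comparisons,
        regional_anova=regional,
        provenance=provenance,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
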