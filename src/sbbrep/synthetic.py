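"""Synthetic surface cohorts with planted structure.

Generates study-shaped data entirely offline: demographics (age, binary
gender, education), a panel of behavioural scores that are mostly null,
and per-vertex cortical-thickness maps carrying spatially contiguous
planted effects plus spatially smooth noise.  Everything is a pure
function of (configuration, seed), so downstream stages — splitting,
exploratory mapping, replication, power — can be exercised and calibrated
without any real data.

Conventions for the default panel (documented as synthetic choices):
baseline thickness 2.5 mm, per-vertex noise SD 0.15 mm, noise smoothed by
three neighbour-averaging iterations to emulate kernel-smoothed maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .surface import SurfaceMesh, build_test_mesh, connected_components, smooth_scalars


@dataclass
class ScoreSpec:
    """Distribution of one behavioural score.

    ``dist`` is ``"normal"`` (mean/sd) or ``"uniform"`` (lo/hi via
    mean +/- sd*sqrt(3)); ``missing_rate`` introduces MCAR missingness.
    """

    name: str
    dist: str = "normal"
    mean: float = 0.0
    sd: float = 1.0
    missing_rate: float = 0.0


@dataclass
class EffectSpec:
    """A planted association between a target variable and thickness.

    The effect lives on a connected vertex ``patch``; its strength is given
    either as ``slope`` (mm of thickness per unit of the target) or as a
    target partial correlation ``r``, which is converted to a slope using
    the realized noise SD: ``slope = r * sd_noise / (sd_target * sqrt(1 - r**2))``.

    Real morphometric effects are not spatially uniform: they peak at a
    core and fade toward the patch boundary.  ``taper`` is the relative
    strength at the most distant patch vertex (1.0 = uniform); intermediate
    vertices are scaled linearly in graph distance from ``center`` (default:
    the lowest-index patch vertex).  The nominal ``slope``/``r`` applies at
    the core.
    """

    target: str
    patch: np.ndarray
    slope: float | None = None
    r: float | None = None
    taper: float = 1.0
    center: int | None = None

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch, dtype=np.int64)
        if (self.slope is None) == (self.r is None):
            raise ValueError("specify exactly one of slope or r")
        if self.r is not None and not -1 < self.r < 1:
            raise ValueError("|r| must be < 1")
        if not 0.0 <= self.taper <= 1.0:
            raise ValueError("taper must lie in [0, 1]")

    def strength_profile(self, mesh: SurfaceMesh) -> np.ndarray:
        """Per-patch-vertex multiplier in (0, 1], 1 at the core."""
        if self.taper >= 1.0:
            return np.ones(self.patch.size)
        center = int(self.patch[0]) if self.center is None else int(self.center)
        dist = _graph_distances(mesh, center, self.patch)
        dmax = dist.max()
        if dmax == 0:
            return np.ones(self.patch.size)
        return 1.0 - (1.0 - self.taper) * dist / dmax


def _graph_distances(mesh: SurfaceMesh, source: int, targets: np.ndarray) -> np.ndarray:
    """BFS hop counts from ``source`` restricted to the ``targets`` patch."""
    in_patch = np.zeros(mesh.n_vertices, dtype=bool)
    in_patch[targets] = True
    dist = np.full(mesh.n_vertices, -1, dtype=np.int64)
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for u in mesh.neighbors(v):
                if in_patch[u] and dist[u] < 0:
                    dist[u] = dist[v] + 1
                    nxt.append(int(u))
        frontier = nxt
    d = dist[targets]
    d[d < 0] = d.max() + 1 if (d >= 0).any() else 1  # unreachable: treat as edge
    return d.astype(float)


@dataclass
class Cohort:
    """Subjects x {demographics, scores, per-vertex thickness}.

    ``phenotypes`` holds ``subject_id, age, gender, education`` plus one
    column per score; ``thickness`` maps hemisphere label to a
    subjects x vertices matrix aligned to the phenotype rows.
    """

    phenotypes: pd.DataFrame
    meshes: dict[str, SurfaceMesh] = field(default_factory=dict)
    thickness: dict[str, np.ndarray] = field(default_factory=dict)
    score_names: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    def confounder_matrix(self, rows=None) -> np.ndarray:
        df = self.phenotypes if rows is None else self.phenotypes.loc[rows]
        return df[["age", "gender", "education"]].to_numpy(dtype=float)

    def subset(self, subject_ids) -> "Cohort":
        idx = self.phenotypes.index.get_indexer(
            self.phenotypes.index[self.phenotypes["subject_id"].isin(subject_ids)]
        )
        pheno = self.phenotypes.iloc[idx].reset_index(drop=True)
        thick = {h: m[idx] for h, m in self.thickness.items()}
        return Cohort(
            phenotypes=pheno,
            meshes=self.meshes,
            thickness=thick,
            score_names=list(self.score_names),
        )

    def write_phenotypes(self, path) -> None:
        self.phenotypes.to_csv(path, index=False)

    def write_thickness(self, hemisphere: str, path) -> None:
        np.savetxt(path, self.thickness[hemisphere], fmt="%.8g", delimiter="\t")


def generate_cohort(
    n: int,
    age_range: tuple[float, float] = (22.0, 37.0),
    age_mean: float = 28.0,
    age_sd: float = 3.7,
    gender_balance: float = 0.5,
    education_mean: float = 15.0,
    education_sd: float = 1.8,
    score_specs: list[ScoreSpec] | None = None,
    seed: int | None = None,
) -> Cohort:
    """Draw demographics and behavioural scores for ``n`` subjects.

    Ages follow a normal distribution truncated to ``age_range``; gender is
    a binary code drawn to match ``gender_balance`` exactly after rounding
    (the study shape is 420 subjects, half female); scores are i.i.d. from
    their configured distributions, independent of demographics.
    """
    if n < 2:
        raise ValueError("need at least two subjects")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError("age range must satisfy lo < hi")
    rng = np.random.default_rng(seed)
    a, b = (lo - age_mean) / age_sd, (hi - age_mean) / age_sd
    age = stats.truncnorm.rvs(a, b, loc=age_mean, scale=age_sd, size=n, random_state=rng)
    n_fem = int(round(n * gender_balance))
    gender = np.zeros(n, dtype=int)
    gender[rng.permutation(n)[:n_fem]] = 1
    education = np.clip(
        rng.normal(education_mean, education_sd, size=n), 8.0, 24.0
    )
    data = {
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age": age,
        "gender": gender,
        "education": education,
    }
    names: list[str] = []
    for spec in score_specs or []:
        if spec.dist == "normal":
            vals = rng.normal(spec.mean, spec.sd, size=n)
        elif spec.dist == "uniform":
            half = spec.sd * np.sqrt(3.0)
            vals = rng.uniform(spec.mean - half, spec.mean + half, size=n)
        else:
            raise ValueError(f"unknown score distribution {spec.dist!r}")
        if spec.missing_rate > 0:
            vals = vals.astype(object)
            miss = rng.random(n) < spec.missing_rate
            vals = np.where(miss, np.nan, vals).astype(float)
        data[spec.name] = vals
        names.append(spec.name)
    return Cohort(phenotypes=pd.DataFrame(data), score_names=names)


def generate_thickness(
    cohort: Cohort,
    mesh: SurfaceMesh,
    baseline_mean: float = 2.5,
    effects: list[EffectSpec] | None = None,
    noise_sd: float = 0.15,
    smooth_iterations: int = 3,
    seed: int | None = None,
) -> Cohort:
    """Fill one hemisphere's thickness matrix with planted effects + noise.

    ``thickness(s, v) = baseline + sum_effects slope * centered(target_s) * 1{v in patch}
    + noise(s, v)`` where the noise is white Gaussian, graph-smoothed for
    spatial autocorrelation, then rescaled per vertex so its realized
    between-subject SD equals ``noise_sd`` exactly (the calibration that
    makes r-specified effect sizes land on target).  With ``noise_sd = 0``
    and a single slope effect, the within-patch OLS slope of thickness on
    the target reproduces the specified slope to machine precision.
    """
    effects = effects or []
    n = cohort.n_subjects
    rng = np.random.default_rng(seed)
    thick = np.full((n, mesh.n_vertices), float(baseline_mean))
    if noise_sd > 0:
        noise = rng.standard_normal((n, mesh.n_vertices))
        if smooth_iterations > 0:
            noise = smooth_scalars(mesh, noise, smooth_iterations)
        sd = noise.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        noise = noise / sd * noise_sd
        thick += noise
    for eff in effects:
        if eff.patch.size == 0 or eff.patch.max() >= mesh.n_vertices:
            raise ValueError("effect patch outside mesh")
        in_patch = np.zeros(mesh.n_vertices, dtype=bool)
        in_patch[eff.patch] = True
        if len(connected_components(mesh, in_patch)) != 1:
            raise ValueError(f"effect patch for {eff.target!r} is not connected")
        target = cohort.phenotypes[eff.target].to_numpy(dtype=float)
        centered = target - np.nanmean(target)
        centered = np.nan_to_num(centered)
        sd_t = centered.std(ddof=0)
        if eff.slope is not None:
            slope = eff.slope
        else:
            if noise_sd <= 0:
                raise ValueError("r-specified effects require noise_sd > 0")
            slope = eff.r * noise_sd / (sd_t * np.sqrt(1.0 - eff.r**2))
        profile = eff.strength_profile(mesh)
        thick[:, eff.patch] += slope * centered[:, None] * profile[None, :]
    cohort.meshes[mesh.hemisphere] = mesh
    cohort.thickness[mesh.hemisphere] = thick
    return cohort


# ---------------------------------------------------------------------------
# Default study panel
# ---------------------------------------------------------------------------

N_SCORES = 34
N_EFFECT_SCORES = 3


def default_study_panel(
    seed: int | None = 0,
    n: int = 420,
    mesh_resolution: int = 2,
    age_effect_r: float = -0.45,
    score_effect_r: float = 0.25,
    patch_size: int = 25,
    noise_sd: float = 0.15,
) -> Cohort:
    """A ready-made cohort matching the study shape.

    420 subjects aged 22-37 (half female), 34 behavioural scores of which
    31 are pure null and 3 carry small planted effects, plus a contiguous
    negative age effect on the left hemisphere — the analogue of the
    strong, spatially consistent age-thickness association used as the
    replicability benchmark.  Two icosphere hemispheres stand in for the
    registered cortical surface.

    Effect scores are ``score_01 .. score_03``; ``score_04`` onward are
    null.  The age patch sits on ``lh``; the score patches are disjoint
    from it and from each other.
    """
    specs = [ScoreSpec(name=f"score_{i + 1:02d}") for i in range(N_SCORES)]
    cohort = generate_cohort(n=n, score_specs=specs, seed=seed)
    lh = build_test_mesh("icosphere", mesh_resolution, hemisphere="lh")
    rh = build_test_mesh("icosphere", mesh_resolution, hemisphere="rh")
    # deterministic, well-separated seed vertices for the planted patches
    from .surface import contiguous_patch

    n_v = lh.n_vertices
    age_patch = contiguous_patch(lh, 0, min(patch_size + 5, n_v // 4))
    taken = set(age_patch.tolist())
    patches = []
    patch_centers = []
    candidates = np.linspace(n_v - 1, 1, num=50, dtype=int)
    for c in candidates:
        if len(patches) == N_EFFECT_SCORES:
            break
        if c in taken:
            continue
        try:
            p = contiguous_patch(lh, int(c), patch_size)
        except Exception:
            continue
        if taken.isdisjoint(p.tolist()):
            patches.append(p)
            patch_centers.append(int(c))
            taken.update(p.tolist())
    effects_lh = [
        EffectSpec(target="age", patch=age_patch, r=age_effect_r, taper=0.15, center=0)
    ]
    for (i, p), c in zip(enumerate(patches), patch_centers):
        effects_lh.append(
            EffectSpec(
                target=f"score_{i + 1:02d}", patch=p, r=score_effect_r,
                taper=0.4, center=int(c),
            )
        )
    seed = 0 if seed is None else seed
    generate_thickness(
        cohort, lh, effects=effects_lh, noise_sd=noise_sd,
        seed=(seed * 1000003 + 1) % 2**31,
    )
    generate_thickness(
        cohort, rh, effects=[], noise_sd=noise_sd,
        seed=(seed * 1000003 + 2) % 2**31,
    )
    cohort.planted = {  # type: ignore[attr-defined]
        "age_patch": age_patch,
        "score_patches": {f"score_{i + 1:02d}": p for i, p in enumerate(patches)},
        "effect_scores": [f"score_{i + 1:02d}" for i in range(len(patches))],
        "null_scores": [f"score_{i + 1:02d}" for i in range(len(patches), N_SCORES)],
    }
    return cohort
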