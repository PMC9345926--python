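"""Study configuration and end-to-end pipeline runs.

A single structured config (YAML) declares the study design — scores,
number of splits, discovery ratios, permutations, alpha, TFCE settings,
master seed — with the study defaults pre-filled (100 splits, ratios
0.70/0.50/0.30, 1000 permutations, alpha 0.05).  ``run_study`` executes
the full design: split, explore, aggregate, replicate, power; every task
derives its own seed from the master seed and its identity, so runs are
reproducible, resumable, and order-independent.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .consistency import aggregate_overlap, density_summary
from .effect_power import PowerRecord, compare_power_groups
from .exploratory import TFCEParams, DesignMatrix, permutation_fwe, extract_clusters
from .replication import replicate_rois, replication_summary
from .splits import SplitPlan, make_splits
from .synthetic import Cohort, default_study_panel

log = logging.getLogger("sbbrep")


def derive_seed(master: int, *tokens) -> int:
    """Stable per-task seed below 2**31, derived from the master seed and
    the task identity (never from worker order)."""
    key = "|".join([str(master), *map(str, tokens)])
    digest = hashlib.sha256(key.encode()).hexdigest()
    return int(digest[:15], 16) % (2**31)


@dataclass
class SyntheticConfig:
    n_subjects: int = 420
    mesh_resolution: int = 2
    age_effect_r: float = -0.45
    score_effect_r: float = 0.25
    noise_sd: float = 0.15


@dataclass
class StudyConfig:
    """Full study declaration; defaults reproduce the reference design."""

    scores: list[str] | None = None  # None -> every score in the cohort
    n_splits: int = 100
    ratios: tuple[float, ...] = (0.70, 0.50, 0.30)
    n_permutations: int = 1000
    alpha: float = 0.05
    tfce: TFCEParams = field(default_factory=TFCEParams)
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    out_dir: str = "results"
    bf_prior_width: float = 1.0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not all(0.0 < r < 1.0 for r in self.ratios):
            raise ValueError("ratios must lie strictly in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        known = {
            "scores", "n_splits", "ratios", "n_permutations", "alpha",
            "tfce", "seed", "synthetic", "out_dir", "bf_prior_width",
        }
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(raw)
        if "tfce" in kw and isinstance(kw["tfce"], dict):
            kw["tfce"] = TFCEParams(**kw["tfce"])
        if "synthetic" in kw and isinstance(kw["synthetic"], dict):
            kw["synthetic"] = SyntheticConfig(**kw["synthetic"])
        if "ratios" in kw:
            kw["ratios"] = tuple(float(r) for r in kw["ratios"])
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def resolve_scores(self, cohort: Cohort) -> list[str]:
        if self.scores is None:
            return list(cohort.score_names)
        missing = [s for s in self.scores if s not in cohort.phenotypes.columns]
        if missing:
            raise ValueError(f"scores not in phenotype table: {missing}")
        return list(self.scores)


def enumerate_analyses(
    config: StudyConfig, cohort: Cohort | None = None
) -> list[tuple[str, float, int]]:
    """Deterministic list of (score, ratio, split_id) exploratory tasks.

    The default design enumerates 34 scores x 3 ratios x 100 splits =
    10,200 whole-brain analyses.
    """
    scores = (
        config.resolve_scores(cohort)
        if cohort is not None
        else (
            config.scores
            if config.scores is not None
            else [f"score_{i + 1:02d}" for i in range(34)]
        )
    )
    if not scores:
        raise ValueError("no scores declared")
    return [
        (score, ratio, split_id)
        for score in scores
        for ratio in config.ratios
        for split_id in range(1, config.n_splits + 1)
    ]


# ---------------------------------------------------------------------------
# Task execution
# ---------------------------------------------------------------------------


def run_exploratory_task(
    cohort: Cohort,
    plan: SplitPlan,
    score: str,
    config: StudyConfig,
) -> dict:
    """One exploratory + confirmatory analysis for (score, ratio, split).

    Fits the discovery-sample GLM, runs permutation TFCE inference with a
    task-specific derived seed, extracts significant clusters, and
    evaluates the three replication criteria on the matched test sample.
    Returns a JSON-serializable task record.
    """
    disc = cohort.subset(plan.discovery_ids)
    test = cohort.subset(plan.test_ids)
    valid = disc.phenotypes[score].notna().to_numpy()
    conf_cols = [c for c in ("age", "gender", "education") if c != score]
    design = DesignMatrix(
        score=disc.phenotypes[score].to_numpy(dtype=float)[valid],
        confounders=disc.phenotypes[conf_cols].to_numpy(dtype=float)[valid],
        score_name=score,
    )
    thickness = {h: m[valid] for h, m in disc.thickness.items()}
    task_seed = derive_seed(config.seed, "explore", score, f"{plan.ratio:.4f}", plan.split_id)
    stat = permutation_fwe(
        thickness, design, cohort.meshes,
        params=config.tfce, n_perm=config.n_permutations, seed=task_seed,
    )
    clusters = extract_clusters(
        stat, cohort.meshes, alpha=config.alpha, score_name=score, split_id=plan.split_id
    )
    records = replicate_rois(
        clusters, score, disc, test,
        ratio=plan.ratio, split_id=plan.split_id,
        alpha=config.alpha, prior_width=config.bf_prior_width,
    )
    sig = {
        h: np.flatnonzero(stat.p_fwe[h] < config.alpha).tolist()
        for h in stat.hemispheres
    }
    return {
        "score": score,
        "ratio": plan.ratio,
        "split_id": plan.split_id,
        "seed": task_seed,
        "n_discovery": len(plan.discovery_ids),
        "n_test": len(plan.test_ids),
        "significant_vertices": sig,
        "clusters": [
            {
                "hemisphere": c.hemisphere,
                "vertices": c.vertices.tolist(),
                "sign": c.sign,
                "peak_t": c.peak_t,
                "min_p": c.min_p,
            }
            for c in clusters
        ],
        "replication": [
            {
                "n_test": len(plan.test_ids),
                **{
                    k: (v.item() if isinstance(v, np.generic) else v)
                    for k, v in vars(r).items()
                },
            }
            for r in records
        ],
    }


def _task_path(out: Path, score: str, ratio: float, split_id: int) -> Path:
    return out / "tasks" / f"{score}_r{ratio:.2f}_s{split_id:03d}.json"


def run_study(
    config: StudyConfig,
    cohort: Cohort | None = None,
    out_dir: str | Path | None = None,
    resume: bool = True,
) -> dict:
    """Execute the full study design and write all result artifacts.

    Layout under ``out_dir``: per-task JSON records (the resume manifest —
    a task with an existing record is skipped), per-(score, ratio) overlap
    maps (TSV) and density summaries (JSON), pooled replication records
    and summary (TSV), power tables (TSV) and the Mann-Whitney power
    comparison (JSON), plus a JSONL event log.  Tasks are independent and
    seeded by identity, so any execution order gives identical results.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    (out / "tasks").mkdir(parents=True, exist_ok=True)
    events = open(out / "events.jsonl", "a")

    def emit(**kw):
        kw["time"] = round(time.time(), 3)
        events.write(json.dumps(kw) + "\n")
        events.flush()

    if cohort is None:
        cohort = default_study_panel(
            seed=derive_seed(config.seed, "panel"),
            n=config.synthetic.n_subjects,
            mesh_resolution=config.synthetic.mesh_resolution,
            age_effect_r=config.synthetic.age_effect_r,
            score_effect_r=config.synthetic.score_effect_r,
            noise_sd=config.synthetic.noise_sd,
        )
    scores = config.resolve_scores(cohort)
    emit(event="start", n_scores=len(scores), n_splits=config.n_splits,
         ratios=list(config.ratios), n_subjects=cohort.n_subjects)

    plans: dict[float, list[SplitPlan]] = {}
    for ratio in config.ratios:
        plans[ratio] = make_splits(
            cohort, ratio, config.n_splits,
            seed=derive_seed(config.seed, "split", f"{ratio:.4f}"),
        )

    tasks = [(s, r, k) for s in scores for r in config.ratios for k in range(1, config.n_splits + 1)]
    for score, ratio, split_id in tasks:
        path = _task_path(out, score, ratio, split_id)
        if resume and path.exists():
            continue
        t0 = time.time()
        try:
            rec = run_exploratory_task(cohort, plans[ratio][split_id - 1], score, config)
        except Exception as exc:  # task-level failure: record and continue
            emit(event="task_failed", score=score, ratio=ratio,
                 split_id=split_id, error=str(exc))
            log.exception("task failed: %s r=%s split=%s", score, ratio, split_id)
            continue
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(rec))
        tmp.rename(path)
        emit(event="task_done", score=score, ratio=ratio, split_id=split_id,
             seed=rec["seed"], n_clusters=len(rec["clusters"]),
             runtime_s=round(time.time() - t0, 3))

    results = aggregate_study(config, cohort, out)
    emit(event="done")
    events.close()
    return results


def aggregate_study(config: StudyConfig, cohort: Cohort, out: Path) -> dict:
    """Build overlap maps, density summaries, replication and power tables
    from the per-task records on disk."""
    out = Path(out)
    scores = config.resolve_scores(cohort)
    hemis = list(cohort.meshes)
    n_v = {h: cohort.meshes[h].n_vertices for h in hemis}
    all_reps: list[dict] = []
    densities: dict[str, dict] = {}
    for score in scores:
        for ratio in config.ratios:
            masks = []
            for split_id in range(1, config.n_splits + 1):
                path = _task_path(out, score, ratio, split_id)
                if not path.exists():
                    continue
                rec = json.loads(path.read_text())
                mask = np.zeros(sum(n_v.values()), dtype=bool)
                offset = 0
                for h in hemis:
                    mask[np.array(rec["significant_vertices"].get(h, []), dtype=int) + offset] = True
                    offset += n_v[h]
                masks.append(mask)
                all_reps.extend(rec["replication"])
            if not masks:
                continue
            overlap = aggregate_overlap(masks, score_name=score)
            dens = density_summary(overlap)
            key = f"{score}_r{ratio:.2f}"
            np.savetxt(out / f"overlap_{key}.tsv", overlap.counts, fmt="%d")
            (out / f"density_{key}.json").write_text(dens.to_json())
            densities[key] = json.loads(dens.to_json())

    summary: dict = {"densities": densities}
    if all_reps:
        rep_df = pd.DataFrame(all_reps)
        rep_df.to_csv(out / "replication_records.tsv", sep="\t", index=False)
        from .replication import ReplicationRecord

        recs = [ReplicationRecord(**{k: r[k] for k in ReplicationRecord.__dataclass_fields__ if k in r})
                for r in all_reps]
        rep_sum = replication_summary(recs)
        rep_sum.to_csv(out / "replication_summary.tsv", sep="\t", index=False)
        summary["replication_summary"] = rep_sum.to_dict(orient="records")

        power_records = [
            PowerRecord(
                roi_id=r["roi_id"], r_discovery=r["r_discovery"],
                n_test=int(r["n_test"]),
                power=r["power"], replicated=bool(r["verdict_significance"]),
                alpha=config.alpha,
            )
            for r in all_reps
            if r.get("power") is not None
        ]
        if power_records:
            pd.DataFrame([vars(p) for p in power_records]).to_csv(
                out / "power_records.tsv", sep="\t", index=False
            )
            if any(p.replicated for p in power_records) and any(
                not p.replicated for p in power_records
            ):
                u, p = compare_power_groups(power_records)
                (out / "power_comparison.json").write_text(
                    json.dumps({"U": u, "p": p})
                )
                summary["power_comparison"] = {"U": u, "p": p}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
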