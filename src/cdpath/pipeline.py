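"""End-to-end orchestration: fit/select -> classify -> pathway -> progression.

``run_pipeline`` executes the full analysis on a response file + Q-matrix
and writes every artifact (fit, selection plan, classification, pathway
graph, progression table, per-student profiles) plus a manifest carrying
the config echo and its hash, so a run is reproducible from the manifest
alone.  All outputs are plain text (CSV / JSON / DOT).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation, pathway as pathway_mod, progression as prog_mod, wald
from .estimation import MixedCDMFit, PosteriorClassification
from .models import ItemParameterSet
from .qmatrix import ResponseMatrix, prune_attributes, read_qmatrix, read_responses

logger = logging.getLogger("cdpath")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "export_student_profiles",
    "fit_to_dict",
    "fit_from_dict",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    responses: str = ""
    qmatrix: str = ""
    out_dir: str = "cdpath_run"
    min_items: int = 3
    alpha: float = 0.05
    prefer_parsimony: bool = False
    top_k: int = 17
    n_tiers: int = 3
    boundaries: list | None = None
    seed: int = 0
    em_tol: float = 1e-4
    em_max_iter: int = 1000
    reliability_reps: int = 0       # 0 skips the reliability simulation
    reliability_n: int = 2000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def fit_to_dict(fit: MixedCDMFit) -> dict:
    return {
        "items": [it.to_dict() for it in fit.items],
        "class_probs": fit.class_probs.tolist(),
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "n_obs": fit.n_obs,
        "n_attributes": fit.n_attributes,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }


def fit_from_dict(d: dict) -> MixedCDMFit:
    return MixedCDMFit(
        items=tuple(ItemParameterSet.from_dict(x) for x in d["items"]),
        class_probs=np.asarray(d["class_probs"], dtype=float),
        loglik=float(d["loglik"]),
        n_params=int(d["n_params"]),
        n_obs=int(d["n_obs"]),
        n_attributes=int(d["n_attributes"]),
        trace=np.asarray(d.get("trace", [d["loglik"]])),
        converged=bool(d["converged"]),
        n_iter=int(d.get("n_iter", 0)),
    )


def export_student_profiles(
    classification: PosteriorClassification,
    data: ResponseMatrix,
    attribute_labels=None,
) -> pd.DataFrame:
    """One row per examinee: MAP state, its posterior mass, raw score, and
    per-attribute posterior mastery — the table behind individual
    strengths/weaknesses radar charts.  Carrying the raw score makes
    same-score / different-state pairs directly discoverable."""
    K = classification.n_attributes
    labels = list(attribute_labels) if attribute_labels is not None else [
        f"A{k + 1}" for k in range(K)
    ]
    df = pd.DataFrame(
        {
            "examinee": classification.examinee_ids,
            "map_state": classification.map_states,
            "map_prob": classification.map_prob,
            "raw_score": data.raw_scores(),
        }
    )
    for k, lab in enumerate(labels):
        df[lab] = classification.marginal_mastery[:, k]
    return df


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write artifacts; returns objects + paths."""
    for name in ("responses", "qmatrix"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise PipelineError(f"stage input-validation: missing {name} file {p!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline config: %s", asdict(config))

    def stage(name, fn):
        try:
            return fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 — rewrap with stage name
            raise PipelineError(f"stage {name}: {exc}") from exc

    q8 = stage("read-qmatrix", lambda: read_qmatrix(config.qmatrix))
    q, removed = stage(
        "prune-qmatrix", lambda: prune_attributes(q8, config.min_items)
    )
    data = stage("read-responses", lambda: read_responses(config.responses))
    if data.n_items != q.n_items:
        raise PipelineError(
            "stage read-responses: response matrix has "
            f"{data.n_items} items but Q-matrix has {q.n_items}"
        )

    plan, fit = stage(
        "fit-select",
        lambda: wald.build_mixed_model(
            data,
            q,
            config.alpha,
            prefer_parsimony=config.prefer_parsimony,
            seed=config.seed,
            tol=config.em_tol,
            max_iter=config.em_max_iter,
        ),
    )
    indices = stage("fit-indices", lambda: estimation.fit_indices(fit, data))
    cls = stage("classify", lambda: estimation.classify(fit, data))

    table = stage("pathway", lambda: pathway_mod.tabulate_states(cls))
    retained, coverage = pathway_mod.top_states(table, config.top_k)
    graph = stage(
        "pathway", lambda: pathway_mod.build_graph(retained, table.total_n)
    )
    dominant = stage("pathway", lambda: pathway_mod.dominant_path(graph))
    graph = pathway_mod.PathwayGraph(
        graph=graph.graph, coverage=coverage, total_n=graph.total_n, dominant=dominant
    )

    rare = {s: c for s, c in table.counts.items() if s not in retained}
    mapping = stage(
        "progression", lambda: prog_mod.assign_rare_states(rare, retained)
    )
    twopl = stage("progression", lambda: prog_mod.fit_2pl(data))
    ability = stage(
        "progression",
        lambda: prog_mod.state_ability_table(cls.map_states, mapping, twopl.theta),
    )
    tiers = stage(
        "progression",
        lambda: prog_mod.set_levels(ability, config.n_tiers, config.boundaries),
    )

    profiles = export_student_profiles(cls, data, q.attribute_labels)

    reliability = None
    if config.reliability_reps > 0:
        per_attr, mean_rel = stage(
            "reliability",
            lambda: estimation.classification_reliability(
                fit, config.reliability_n, config.reliability_reps, config.seed
            ),
        )
        reliability = {
            "per_attribute": dict(zip(q.attribute_labels, map(float, per_attr))),
            "mean": mean_rel,
        }

    artifacts = {}

    def emit(name, writer):
        path = out / name
        writer(path)
        artifacts[name] = str(path)

    emit("fit.json", lambda p: _write_json(
        {
            **fit_to_dict(fit),
            "pruned_attributes": list(removed),
            "fit_indices": {
                "aic": indices.aic,
                "bic": indices.bic,
                "deviance": indices.deviance,
                "rmsea": indices.rmsea,
                "cronbach_alpha": indices.cronbach_alpha,
            },
            **({"reliability": reliability} if reliability else {}),
        },
        p,
    ))
    emit("plan.json", lambda p: _write_json(plan.to_dict(), p))
    emit("classification.csv", lambda p: profiles.to_csv(p, index=False))
    emit("pathway.json", lambda p: _write_json(graph.to_dict(), p))
    emit("pathway.dot", lambda p: p.write_text(graph.to_dot() + "\n"))
    emit("progression.csv", lambda p: tiers.rows.to_csv(p, index=False))

    manifest = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "artifacts": sorted(artifacts),
        "n_examinees": data.n_examinees,
        "n_items": q.n_items,
        "n_attributes": q.n_attributes,
        "dominant_path": list(dominant),
        "coverage": coverage,
        "tier_boundaries": list(tiers.boundaries),
    }
    _write_json(manifest, out / "manifest.json")
    artifacts["manifest.json"] = str(out / "manifest.json")

    return {
        "qmatrix": q,
        "removed_attributes": removed,
        "data": data,
        "plan": plan,
        "fit": fit,
        "fit_indices": indices,
        "classification": cls,
        "state_table": table,
        "graph": graph,
        "dominant_path": dominant,
        "cluster_mapping": mapping,
        "twopl": twopl,
        "progression": tiers,
        "profiles": profiles,
        "reliability": reliability,
        "artifacts": artifacts,
    }
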