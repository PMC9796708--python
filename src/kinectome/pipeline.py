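"""End-to-end study orchestration.

Runs the full analysis chain on a cohort (loaded from disk or generated
synthetically): kinectome construction, group mean/variability comparison,
modularity with consensus clustering and allegiance matrices, test-retest
fingerprinting, ICC-based edge selection with null identification-rate
curves, node-occurrence significance, nodal degree comparison, and the
clinical prediction model.  Every stage derives its seed deterministically
from the master seed, all matrices are written as labeled delimited text,
and the summary report is byte-stable for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, edge_select, fingerprint, modularity, network, stats, synth
from .io import AXES, MarkerTrial, load_subjects, read_trial, validate_session
from .kinematics import QUANTITIES
from .markers import default_marker_set

__all__ = ["StudyConfig", "run_study"]

log = logging.getLogger("kinectome")


@dataclass
class StudyConfig:
    """Configuration of one study run.

    Either ``synthetic`` (one or more cohort specs, e.g. a healthy and a
    parkinsonian one) or ``trials_dir`` + ``subjects_csv`` must be given.
    Trial files in ``trials_dir`` are named ``<subject>_<session>.csv``
    (delimited) or ``.c3d``.
    """

    output_dir: str = "kinectome_study"
    synthetic: list[synth.CohortSpec] | None = None
    trials_dir: str | None = None
    subjects_csv: str | None = None
    trial_format: str = "delimited"
    quantities: tuple[str, ...] = QUANTITIES
    axes: tuple[str, ...] = AXES
    filter_cutoff_hz: float | None = None
    n_perm: int = 10000
    consensus_iters: int = 100
    n_null_curves: int = 100
    ir_threshold: float = 0.99
    node_pool_axes: tuple[str, ...] = ("ML", "AP")
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.axes) <= set(AXES):
            raise ValueError(f"axes must be a subset of {AXES}")
        if not set(self.quantities) <= set(QUANTITIES):
            raise ValueError(f"quantities must be a subset of {QUANTITIES}")
        for name in ("n_perm", "consensus_iters", "n_null_curves", "k_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            doc = json.load(fh)
        if "synthetic" in doc and doc["synthetic"] is not None:
            doc["synthetic"] = [
                synth.CohortSpec(**spec) for spec in doc["synthetic"]
            ]
        for key in ("quantities", "axes", "node_pool_axes"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = np.random.SeedSequence([master, zlib.crc32(stage.encode())])
    return int(h.generate_state(1)[0] % (2**31))


_STAGES = ("simulate", "build", "modularity", "fingerprint", "edges",
           "topology", "predict")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_matrix(path: Path, matrix: np.ndarray, labels) -> None:
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(
        path, float_format="%.10g"
    )


def _load_trials(config: StudyConfig) -> tuple[list[MarkerTrial], pd.DataFrame]:
    subjects = load_subjects(config.subjects_csv)
    marker_set = default_marker_set()
    suffix = "csv" if config.trial_format == "delimited" else "c3d"
    trials = []
    for sid in subjects["subject_id"].astype(str):
        for session in ("test", "retest"):
            path = Path(config.trials_dir) / f"{sid}_{session}.{suffix}"
            trials.append(
                read_trial(path, subject_id=sid, session=session,
                           format=config.trial_format, marker_set=marker_set)
            )
    return trials, subjects


def run_study(config: StudyConfig, until: str = "predict") -> dict:
    """Run the study stages in order and write the report bundle.

    ``until`` stops after the named stage (one of ``simulate``, ``build``,
    ``modularity``, ``fingerprint``, ``edges``, ``topology``, ``predict``),
    letting the CLI expose each stage as a verb.
    """
    if until not in _STAGES:
        raise ValueError(f"unknown stage {until!r}")
    last = _STAGES.index(until)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "study.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"config": _config_dict(config), "stages": {}}

    try:
        stage = "simulate"
        t0 = time.perf_counter()
        if config.synthetic is not None:
            trials, subjects = [], []
            for spec in config.synthetic:
                tr, su = synth.generate_cohort(spec)
                trials.extend(tr)
                subjects.append(su)
            subjects = pd.concat(subjects, ignore_index=True)
            log.info("simulate: %d subjects (seed per spec)", len(subjects))
        elif config.trials_dir and config.subjects_csv:
            trials, subjects = _load_trials(config)
        else:
            raise ValueError(
                "config needs either synthetic cohort specs or input paths"
            )
        pairs = validate_session(trials, subjects)
        subjects.to_csv(out / "subjects.csv", index=False)
        report["stages"]["simulate"] = {
            "n_subjects": len(pairs),
            "groups": sorted(set(subjects["group"])),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        runners = {
            "build": _stage_build,
            "modularity": _stage_modularity,
            "fingerprint": _stage_fingerprint,
            "edges": _stage_edges,
            "topology": _stage_topology,
            "predict": _stage_predict,
        }
        for stage in _STAGES[1:last + 1]:
            if stage == "build":
                report["stages"][stage] = _stage_build(
                    config, pairs, subjects, out
                )
            else:
                report["stages"][stage] = runners[stage](
                    config, subjects, out
                )
    except Exception as err:  # keep partial outputs, name the stage
        _dump_report(report, out)
        raise RuntimeError(f"study failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()

    _dump_report(report, out)
    return report


def _config_dict(config: StudyConfig) -> dict:
    doc = asdict(config)
    if config.synthetic is not None:
        specs = []
        for spec in config.synthetic:
            d = asdict(spec)
            d.pop("marker_set")
            specs.append(d)
        doc["synthetic"] = specs
    return doc


def _dump_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
    with open(out / "report.txt", "w") as fh:
        fh.write(_human_report(report))


# per-run caches keyed by output dir contents; kept module-private and
# repopulated by each stage from disk-written artifacts would be wasteful,
# so stages communicate through this in-memory store instead.
_STORE: dict = {}


def _stage_build(config, pairs, subjects, out: Path) -> dict:
    t0 = time.perf_counter()
    kins: dict = {}
    edges: dict = {}
    for sid, (test, retest) in sorted(pairs.items()):
        for trial in (test, retest):
            km = network.trial_kinectomes(
                trial, config.quantities, config.axes,
                filter_cutoff_hz=config.filter_cutoff_hz,
            )
            for (q, a), k in km.items():
                kins[(sid, trial.session, q, a)] = k
                edges[(sid, trial.session, q, a)] = network.vectorize(k)
    kdir = out / "kinectomes"
    kdir.mkdir(exist_ok=True)
    for (sid, session, q, a), k in kins.items():
        k.to_csv(kdir / f"{sid}_{session}_{q}_{a}.csv")
    _STORE.clear()
    _STORE["kins"] = kins
    _STORE["edges"] = edges
    _STORE["subject_order"] = sorted(pairs)

    # group mean / variability comparisons (first two groups, test session)
    result: dict = {
        "n_kinectomes_per_trial": len(config.quantities) * len(config.axes),
        "comparisons": {},
    }
    groups = sorted(set(subjects["group"]))
    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        sid_a = _group_sids(subjects, ga)
        sid_b = _group_sids(subjects, gb)
        n_tests = len(config.quantities) * len(config.axes)
        cutoff = stats.bonferroni_cutoff(0.05, n_tests)
        seed = _stage_seed(config.seed, "build")
        for q in config.quantities:
            for a in config.axes:
                ka = [_STORE["kins"][(s, "test", q, a)] for s in sid_a]
                kb = [_STORE["kins"][(s, "test", q, a)] for s in sid_b]
                mean_res = network.compare_group_means(
                    ka, kb, n_perm=config.n_perm, seed=seed
                )
                sd_res = network.compare_group_variability(
                    ka, kb, n_perm=config.n_perm, seed=seed + 1
                )
                result["comparisons"][f"{q}_{a}"] = {
                    "mean_p": mean_res.p_value,
                    "sd_p": sd_res.p_value,
                    "sd_observed": sd_res.observed_stat,
                    "bonferroni_cutoff": cutoff,
                    "mean_significant": mean_res.p_value < cutoff,
                    "sd_significant": sd_res.p_value < cutoff,
                }
    result["seconds"] = round(time.perf_counter() - t0, 3)
    log.info("build: %d kinectomes", len(kins))
    return result


def _group_sids(subjects: pd.DataFrame, group: str) -> list[str]:
    return sorted(
        subjects.loc[subjects["group"] == group, "subject_id"].astype(str)
    )


def _stage_modularity(config, subjects, out: Path) -> dict:
    t0 = time.perf_counter()
    seed = _stage_seed(config.seed, "modularity")
    result: dict = {}
    mdir = out / "modularity"
    mdir.mkdir(exist_ok=True)
    groups = sorted(set(subjects["group"]))
    for group in groups:
        sids = _group_sids(subjects, group)
        result[group] = {}
        for a in config.axes:
            partitions = []
            for sid in sids:
                for q in config.quantities:
                    k = _STORE["kins"][(sid, "test", q, a)]
                    adj = modularity.to_adjacency(k)
                    partitions.append(
                        modularity.louvain(adj, seed=seed)
                    )
            alleg = modularity.allegiance(partitions)
            part = modularity.group_communities(
                alleg, seed=seed, n_iter=config.consensus_iters
            )
            labels = _STORE["kins"][(sids[0], "test",
                                     config.quantities[0], a)].labels
            _write_matrix(mdir / f"allegiance_{group}_{a}.csv",
                          alleg.matrix, labels)
            pd.DataFrame(
                {"marker": labels, "community": part.community_id}
            ).to_csv(mdir / f"communities_{group}_{a}.csv", index=False)
            result[group][a] = {
                "n_communities": part.n_communities,
                "q": part.q_value,
                "communities": {
                    lab: int(c) for lab, c in zip(labels, part.community_id)
                },
                "seed": seed,
            }
    result["seconds"] = round(time.perf_counter() - t0, 3)
    log.info("modularity done (seed %d)", seed)
    return result


def _fingerprint_inputs(config, subjects, group):
    sids = _group_sids(subjects, group)
    for q in config.quantities:
        for a in config.axes:
            test = [_STORE["edges"][(s, "test", q, a)] for s in sids]
            retest = [_STORE["edges"][(s, "retest", q, a)] for s in sids]
            yield q, a, test, retest


def _stage_fingerprint(config, subjects, out: Path) -> dict:
    t0 = time.perf_counter()
    seed = _stage_seed(config.seed, "fingerprint")
    fdir = out / "fingerprint"
    fdir.mkdir(exist_ok=True)
    result: dict = {}
    per_subject: dict = {}
    groups = sorted(set(subjects["group"]))
    for group in groups:
        result[group] = {}
        for q, a, test, retest in _fingerprint_inputs(config, subjects, group):
            im = fingerprint.identifiability_matrix(test, retest)
            scores = fingerprint.fingerprint_scores(im)
            _write_matrix(fdir / f"im_{group}_{q}_{a}.csv", im.matrix,
                          im.subject_order)
            result[group][f"{q}_{a}"] = {
                "iself": scores.iself,
                "iothers": scores.iothers,
                "idiff": scores.idiff,
                "idiff_percent": scores.idiff * 100,
                "ir": scores.ir,
                "ir_percent": scores.ir * 100,
            }
            per_subject[(group, q, a)] = scores
    _STORE["fingerprint_scores"] = per_subject

    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        n_tests = 3 * len(config.quantities) * len(config.axes)
        cutoff = stats.bonferroni_cutoff(0.05, n_tests)
        comparisons = {}
        for q in config.quantities:
            for a in config.axes:
                sa = per_subject[(ga, q, a)]
                sb = per_subject[(gb, q, a)]
                for name in ("iself", "iothers"):
                    res = fingerprint.compare_fingerprints(
                        getattr(sa, f"{name}_per_subject"),
                        getattr(sb, f"{name}_per_subject"),
                        n_perm=config.n_perm,
                        seed=seed,
                    )
                    comparisons[f"{name}_{q}_{a}"] = {
                        "p": res.p_value,
                        "significant": res.p_value < cutoff,
                    }
        result["comparisons"] = comparisons
        result["bonferroni_cutoff"] = cutoff
    result["seconds"] = round(time.perf_counter() - t0, 3)
    log.info("fingerprint done (seed %d)", seed)
    return result


def _stage_edges(config, subjects, out: Path) -> dict:
    t0 = time.perf_counter()
    seed = _stage_seed(config.seed, "edges")
    edir = out / "edges"
    edir.mkdir(exist_ok=True)
    result: dict = {}
    edge_sets: dict = {}
    groups = sorted(set(subjects["group"]))
    for group in groups:
        result[group] = {}
        edge_sets[group] = {}
        for q, a, test, retest in _fingerprint_inputs(config, subjects, group):
            icc = edge_select.edge_icc(test, retest)
            order = edge_select.icc_edge_order(icc)
            curve = edge_select.ir_curve(test, retest, order)
            null = edge_select.null_ir_curves(
                test, retest, n_null=config.n_null_curves, seed=seed
            )
            curve.null_mean = null["mean"]
            curve.null_p99 = null["p99"]
            interest = edge_select.edges_of_interest(
                curve, ir_threshold=config.ir_threshold
            )
            edge_sets[group][(q, a)] = interest
            pairs = test[0].edge_index
            pd.DataFrame({
                "count": curve.edge_counts,
                "ir": curve.ir_values,
                "null_mean": null["mean"],
                "null_p99": null["p99"],
            }).to_csv(edir / f"ircurve_{group}_{q}_{a}.csv", index=False)
            pd.DataFrame({
                "marker_i": [pairs[e][0] for e in interest],
                "marker_j": [pairs[e][1] for e in interest],
                "icc": [icc.per_edge_icc[e] for e in interest],
            }).to_csv(edir / f"edges_of_interest_{group}_{q}_{a}.csv",
                      index=False)
            result[group][f"{q}_{a}"] = {
                "n_edges_to_threshold": int(len(interest)),
                "full_ir": float(curve.ir_values[-1]),
                "dominates_null_mean": bool(
                    np.all(curve.ir_values >= null["mean"])
                ),
            }
        # node occurrence over the informative (ML/AP) parameters
        labels = _STORE["kins"][
            (_group_sids(subjects, group)[0], "test",
             config.quantities[0], config.axes[0])
        ].labels
        pooled = [
            edge_sets[group][(q, a)]
            for q in config.quantities
            for a in config.node_pool_axes
            if (q, a) in edge_sets[group] and len(edge_sets[group][(q, a)])
        ]
        if pooled:
            pairs = network.edge_index_pairs(tuple(labels))
            occ = edge_select.node_occurrence_significance(
                pooled, pairs, labels, n_null=min(config.n_perm, 10000),
                seed=seed,
            )
            node_occ = {
                "flagged": occ["flagged"],
                "occurrences": occ["occurrences"],
            }
            result[group]["node_occurrence"] = node_occ
            _STORE.setdefault("node_occurrence", {})[group] = node_occ
    _STORE["edge_sets"] = edge_sets
    result["seconds"] = round(time.perf_counter() - t0, 3)
    log.info("edges done (seed %d)", seed)
    return result


def _headline_feature(config, result_edges: dict, group: str):
    """Pick (marker, quantity, axis) from the flagged nodes of a group."""
    node_info = result_edges.get(group, {}).get("node_occurrence")
    if not node_info or not node_info["flagged"]:
        return None
    flagged = node_info["flagged"]
    occ = node_info["occurrences"]
    marker = max(flagged, key=lambda m: occ[m])
    # attribute the marker to the pooled parameter where it occurs most
    best, best_count = None, -1
    for q in config.quantities:
        for a in config.node_pool_axes:
            edges = _STORE["edge_sets"][group].get((q, a))
            if edges is None or not len(edges):
                continue
            labels = _STORE["kins"][
                (_STORE["subject_order"][0], "test", q, a)
            ].labels
            pairs = network.edge_index_pairs(labels)
            count = sum(marker in pairs[e] for e in edges)
            if count > best_count:
                best, best_count = (q, a), count
    return (marker,) + best


def _stage_topology(config, subjects, out: Path) -> dict:
    t0 = time.perf_counter()
    seed = _stage_seed(config.seed, "topology")
    groups = sorted(set(subjects["group"]))
    target_group = "PD" if "PD" in groups else groups[-1]
    edges_result = {
        g: {"node_occurrence": v}
        for g, v in _STORE.get("node_occurrence", {}).items()
    }
    feature = _headline_feature(config, edges_result, target_group)
    result: dict = {"feature": None}
    if feature is None:
        result["note"] = "no marker flagged above chance; degree stage skipped"
        result["seconds"] = round(time.perf_counter() - t0, 3)
        return result
    marker, q, a = feature
    result["feature"] = {"marker": marker, "quantity": q, "axis": a}

    degrees = {}
    for group in groups:
        sids = _group_sids(subjects, group)
        degrees[group] = [
            clinical.weighted_degree(_STORE["kins"][(s, "test", q, a)])
            for s in sids
        ]
        result.setdefault("mean_degree", {})[group] = float(
            np.mean([d[marker] for d in degrees[group]])
        )
    if len(groups) >= 2:
        other = [g for g in groups if g != target_group][0]
        res = clinical.compare_degree(
            degrees[other], degrees[target_group], marker,
            n_perm=config.n_perm, seed=seed,
        )
        result["group_comparison"] = {
            "groups": [other, target_group],
            "p": res.p_value,
            "observed": res.observed_stat,
        }
    # association with the clinical score within the target group
    sids = _group_sids(subjects, target_group)
    scores = subjects.set_index("subject_id").loc[sids, "motor_score"]
    deg_values = [d[marker] for d in degrees[target_group]]
    if len(sids) >= 4 and scores.nunique() > 1:
        rho, p = stats.spearman_corr(deg_values, scores.to_numpy())
        result["spearman"] = {"rho": rho, "p": p}
    _STORE["headline"] = (marker, q, a, target_group, deg_values)
    result["seconds"] = round(time.perf_counter() - t0, 3)
    log.info("topology done (seed %d)", seed)
    return result


def _stage_predict(config, subjects, out: Path) -> dict:
    t0 = time.perf_counter()
    seed = _stage_seed(config.seed, "predict")
    if "headline" not in _STORE:
        return {"note": "no headline feature; prediction skipped",
                "seconds": round(time.perf_counter() - t0, 3)}
    marker, q, a, target_group, deg_values = _STORE["headline"]
    sids = _group_sids(subjects, target_group)
    meta = subjects.set_index("subject_id").loc[sids]
    if len(sids) < 2 * config.k_folds or meta["motor_score"].nunique() < 2:
        return {"note": "target group too small/degenerate for prediction",
                "seconds": round(time.perf_counter() - t0, 3)}
    features = pd.DataFrame({
        "degree": deg_values,
        "age": meta["age"].to_numpy(),
        "education": meta["education"].to_numpy(),
        "gender": meta["sex"].to_numpy(),
    })
    model = clinical.fit_clinical_model(
        features, meta["motor_score"].to_numpy(),
        k=config.k_folds, seed=seed,
    )
    pd.DataFrame({
        "subject_id": sids,
        "observed": meta["motor_score"].to_numpy(),
        "cv_predicted": model.cv_predictions,
        "cv_residual": model.cv_residuals,
    }).to_csv(out / "predictions.csv", index=False)
    result = {
        "feature": {"marker": marker, "quantity": q, "axis": a},
        "coefficients": model.coefficients,
        "p_values": model.p_values,
        "r_squared": model.r_squared,
        "cv_r_squared": model.cv_r_squared,
        "vif": model.vif,
        "k": model.k,
        "seed": seed,
        "warnings": model.warnings,
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("predict done (seed %d)", seed)
    return result


def _human_report(report: dict) -> str:
    lines = ["Kinectome study report", "=" * 24]
    stages = report.get("stages", {})
    if "simulate" in stages:
        s = stages["simulate"]
        lines.append(f"Subjects: {s['n_subjects']} ({', '.join(s['groups'])})")
    if "build" in stages:
        lines.append(
            f"Kinectome types per trial: {stages['build']['n_kinectomes_per_trial']}"
        )
        for name, c in stages["build"].get("comparisons", {}).items():
            lines.append(
                f"  {name}: SD p={c['sd_p']:.4g}"
                f"{' *' if c['sd_significant'] else ''}"
                f" (cutoff {c['bonferroni_cutoff']:.4g})"
            )
    if "fingerprint" in stages:
        for group, block in stages["fingerprint"].items():
            if not isinstance(block, dict) or group in (
                "comparisons",
            ):
                continue
            for name, sc in block.items():
                if isinstance(sc, dict) and "ir_percent" in sc:
                    lines.append(
                        f"  IR {group} {name}: {sc['ir_percent']:.1f}%"
                        f" (I-diff {sc['idiff_percent']:.1f}%)"
                    )
    if "predict" in stages and "r_squared" in stages["predict"]:
        p = stages["predict"]
        lines.append(
            f"Prediction: R2={p['r_squared']:.3f}, "
            f"CV R2={p['cv_r_squared']:.3f}, "
            f"degree beta={p['coefficients']['degree']:.3f}"
        )
    return "\n".join(lines) + "\n"
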