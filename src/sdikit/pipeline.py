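"""End-to-end orchestration of the decoupling analysis.

Chains the stages -- structural normalization and harmonics, SDI
computation, covariate-adjusted group maps, spatial associations,
transcriptome PLS, and SVM classification -- over a cohort directory,
writing every artifact as labeled TSV plus a JSON provenance sidecar
(input hashes, seeds, cutoffs) and one aggregated JSON report.  All
randomness flows from seeds named in the config; reports carry no
timestamps, so identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import gsp, io, spatial, stats, structural, transcriptomics

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("sdikit")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


@dataclass
class PipelineConfig:
    cohort_dir: str
    out_dir: str
    expression_path: str | None = None
    annotation_dir: str | None = None
    term_dir: str | None = None
    gene_sets_path: str | None = None
    stages: tuple[str, ...] = ("structural", "sdi", "compare", "assoc", "pls", "classify")
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 500
    n_components: int = 5
    seed: int = 0
    basis_mode: str = "per-group"  # or "pooled"
    cutoff_rule: str = "median-energy"
    svm_c: float = 10.0
    svm_gamma: float = 0.1
    n_folds: int = 10

    def validate(self) -> None:
        if self.basis_mode not in ("per-group", "pooled"):
            raise ValueError(f"unknown basis_mode '{self.basis_mode}'")
        unknown = set(self.stages) - {"structural", "sdi", "compare", "assoc", "pls", "classify"}
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _group_bases(cohort, config):
    """Build the harmonic basis (and cutoff) each subject decomposes on."""
    volumes = cohort.parcellation.volume
    normalized = [structural.volume_normalize(sc, volumes) for sc in cohort.connectome]
    bases = {}
    if config.basis_mode == "pooled":
        A, _ = structural.symmetric_normalize(structural.group_average(normalized))
        b = structural.harmonics(A, source="pooled")
        bases = {0: b, 1: b}
    else:
        for g, name in ((1, "patient"), (0, "control")):
            members = [m for m, grp in zip(normalized, cohort.group) if grp == g]
            A, _ = structural.symmetric_normalize(structural.group_average(members))
            bases[g] = structural.harmonics(A, source=name)
    return bases


def cohort_sdi_maps(
    cohort, basis_mode: str = "per-group", cutoff: int | None = None
) -> tuple[np.ndarray, int, dict]:
    """Per-subject SDI maps for a cohort.

    Signals are decomposed on each subject's own group basis; the
    median-energy cutoff is estimated once from all subjects pooled (a
    group-specific cutoff would make SDI incomparable across groups, for
    the same reason a per-subject cutoff would across subjects).

    Returns (subjects x regions SDI, cutoff used, bases by group).
    """
    class _Cfg:
        pass

    cfg = _Cfg()
    cfg.basis_mode = basis_mode
    bases = _group_bases(cohort, cfg)
    coeffs = [
        gsp.gft(gsp.zscore(ts), bases[g])
        for ts, g in zip(cohort.timeseries, cohort.group)
    ]
    if cutoff is None:
        cutoff = gsp.median_energy_cutoff(coeffs)
    maps = np.zeros((cohort.n_subjects, cohort.parcellation.n_regions))
    for s, c in enumerate(coeffs):
        x_c, x_d = gsp.split_filter(c, cutoff)
        maps[s] = gsp.sdi(x_c, x_d)
    return maps, int(cutoff), bases


def _stage_sdi(cohort, config, out: Path) -> dict:
    sdi_maps, cutoff, bases = cohort_sdi_maps(cohort, config.basis_mode)
    regions = [str(r) for r in cohort.parcellation.region_id]
    io.write_matrix_tsv(sdi_maps, cohort.subject_id, regions, out / "sdi.tsv")
    prov = {
        "basis_mode": config.basis_mode,
        "cutoff_rule": config.cutoff_rule,
        "cutoff": cutoff,
        "cutoff_eigenvalue": {
            str(g): float(b.eigenvalues[cutoff - 1]) for g, b in bases.items()
        },
    }
    _write_json(prov, out / "sdi_provenance.json")
    return {"cutoff": cutoff, "sdi_maps": sdi_maps}


def _stage_compare(cohort, sdi_maps, config, out: Path) -> dict:
    covars = pd.DataFrame(
        {
            "group": cohort.group,
            "gender": cohort.gender,
            "mean_fd": cohort.mean_fd,
            "severity": cohort.severity,
        }
    )
    tmap = stats.group_glm_tmap(sdi_maps, covars)
    mask = stats.bonferroni_mask(tmap, config.alpha)
    regions = [str(r) for r in cohort.parcellation.region_id]
    table = np.column_stack([tmap.t, tmap.p, mask["mask"].astype(float)])
    io.write_matrix_tsv(table, regions, ["t", "p", "significant"], out / "tmap.tsv")
    block = {
        "n_regions": tmap.n_regions,
        "n_significant": int(mask["mask"].sum()),
        "n_higher": int(mask["higher"].sum()),
        "n_lower": int(mask["lower"].sum()),
        "bonferroni_threshold": mask["threshold"],
        "df": tmap.df,
    }
    sig = np.flatnonzero(mask["mask"])
    if len(sig) and np.isfinite(covars["severity"]).sum() >= 3:
        sev = stats.severity_correlation(sdi_maps, covars, sig)
        sev.to_csv(out / "severity_correlation.tsv", sep="\t", index=False)
        block["severity_significant_regions"] = int(sev["significant"].sum())
    # degree-SDI association per group on the group-mean connectome
    degree_corr = {}
    for g, name in ((1, "patient"), (0, "control")):
        members = [m for m, grp in zip(cohort.connectome, cohort.group) if grp == g]
        if not members:
            continue
        degree = structural.nodal_degree(structural.group_average(members))
        mean_sdi = sdi_maps[cohort.group == g].mean(axis=0)
        r, p = stats.degree_sdi_correlation(degree, mean_sdi)
        degree_corr[name] = {"r": r, "p": p}
    block["degree_sdi"] = degree_corr
    return block | {"tmap": tmap, "mask": mask}


def _read_map_dir(directory: Path, n: int) -> dict[str, np.ndarray]:
    maps = {}
    for path in sorted(directory.glob("*.tsv")):
        values, _, _ = io.read_matrix_tsv(path)
        if values.shape != (n, 1) and values.shape != (1, n):
            raise ValueError(f"{path}: expected a length-{n} map, got shape {values.shape}")
        maps[path.stem] = values.ravel()
    if not maps:
        raise ValueError(f"no .tsv annotation maps found in {directory}")
    return maps


def _stage_assoc(cohort, compare_block, config, out: Path) -> dict:
    maps = _read_map_dir(Path(config.annotation_dir), cohort.parcellation.n_regions)
    null = spatial.spin_rotations(cohort.parcellation, config.n_perm, seed=config.seed)
    directions = spatial.split_tmap_directions(
        compare_block["tmap"].t, compare_block["mask"]["mask"]
    )
    n_corr = len(maps)
    rows = []
    for direction, dmap in directions.items():
        if np.isfinite(dmap).sum() < 3:
            continue
        for label, amap in maps.items():
            res = spatial.spatial_association(dmap, amap, null, n_corr=n_corr, label=label)
            rows.append(
                {
                    "direction": direction,
                    "map": label,
                    "rho": res.rho,
                    "fisher_z": res.fisher_z,
                    "p": res.p,
                    "significant": res.significant,
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(out / "associations.tsv", sep="\t", index=False)
    block: dict = {
        "n_maps": n_corr,
        "n_perm": config.n_perm,
        "threshold": 1.0 / n_corr,
        "n_significant": int(table["significant"].sum()) if len(table) else 0,
    }
    if config.term_dir:
        terms = _read_map_dir(Path(config.term_dir), cohort.parcellation.n_regions)
        for direction, dmap in directions.items():
            if np.isfinite(dmap).sum() < 3:
                continue
            ranked = spatial.decode_term_maps(dmap, terms)
            ranked.to_csv(out / f"terms_{direction}.tsv", sep="\t", index=False)
            block[f"top_term_{direction}"] = str(ranked.iloc[0]["term"])
    return block


def _stage_pls(cohort, compare_block, config, out: Path) -> dict:
    X, genes, _ = _load_expression(Path(config.expression_path))
    if X.shape[0] != cohort.parcellation.n_regions:
        raise ValueError(
            f"expression has {X.shape[0]} regions, cohort has {cohort.parcellation.n_regions}"
        )
    y = compare_block["tmap"].t
    model = transcriptomics.pls_fit(X, y, config.n_components, genes=genes)
    null = spatial.spin_rotations(cohort.parcellation, config.n_perm, seed=config.seed + 1)
    spin_p = transcriptomics.component_spin_test(X, y, null, config.n_components)
    best = int(np.argmax(model.explained_variance))
    table = transcriptomics.bootstrap_gene_z(
        X, y, genes, component=best, n_boot=config.n_boot,
        seed=config.seed + 2, n_components=config.n_components,
    )
    table.to_csv(out / "gene_table.tsv", sep="\t", index=False)
    ev = pd.DataFrame(
        {
            "component": np.arange(1, config.n_components + 1),
            "explained_variance_pct": model.explained_variance,
            "spin_p": spin_p,
        }
    )
    ev.to_csv(out / "pls_components.tsv", sep="\t", index=False)
    block = {
        "component_used": best + 1,
        "explained_variance_pct": float(model.explained_variance[best]),
        "spin_p": float(spin_p[best]),
        "n_pls_plus": int((table["list"] == "PLS1+").sum()),
        "n_pls_minus": int((table["list"] == "PLS1-").sum()),
        "n_boot": config.n_boot,
    }
    if config.gene_sets_path:
        sets = json.loads(Path(config.gene_sets_path).read_text())
        cmp_table = transcriptomics.gene_set_weight_comparison(
            table, sets, n_perm=config.n_perm, seed=config.seed + 3
        )
        cmp_table.to_csv(out / "gene_set_comparison.tsv", sep="\t", index=False)
        block["n_set_pairs"] = len(cmp_table)
    return block


def _load_expression(path: Path):
    values, rlab, genes = io.read_matrix_tsv(path)
    return values, genes, rlab


def _stage_classify(cohort, sdi_maps, config, out: Path) -> dict:
    covars = pd.DataFrame(
        {"group": cohort.group, "gender": cohort.gender, "mean_fd": cohort.mean_fd}
    )
    cv = _classify.run_cv(
        sdi_maps,
        covars,
        _classify.CVConfig(
            n_folds=config.n_folds, c=config.svm_c, gamma=config.svm_gamma,
            alpha=config.alpha, seed=config.seed,
        ),
    )
    cv.fold_metrics.to_csv(out / "cv_folds.tsv", sep="\t", index=False)
    cv.stability.to_csv(out / "cv_stability.tsv", sep="\t", index=False)
    means = cv.mean_metrics
    return {
        "mean_acc": means["acc"],
        "mean_sen": means["sen"],
        "mean_spe": means["spe"],
        "mean_auc": means["auc"],
        "n_stable_features": int(cv.stability["stable"].sum()),
        "n_skipped_folds": int(cv.fold_metrics["skipped"].sum()),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the aggregated JSON report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_dir = Path(config.cohort_dir)
    report: dict = {
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "inputs": {
            "cohort_subjects_sha256": _sha256(cohort_dir / "subjects.tsv"),
            "cohort_parcellation_sha256": _sha256(cohort_dir / "parcellation.tsv"),
        },
        "stages": {},
    }
    try:
        cohort = io.read_cohort(cohort_dir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", str(exc)) from exc

    sdi_maps = None
    compare_block = None
    for stage in ("structural", "sdi", "compare", "assoc", "pls", "classify"):
        if stage not in config.stages:
            continue
        log.info("[%s] running", stage)
        try:
            if stage == "structural":
                bases = _group_bases(cohort, config)
                for g, b in bases.items():
                    io.write_basis(b, out / f"basis_group{g}")
                report["stages"]["structural"] = {
                    "basis_mode": config.basis_mode,
                    "n_regions": cohort.parcellation.n_regions,
                }
            elif stage == "sdi":
                res = _stage_sdi(cohort, config, out)
                sdi_maps = res["sdi_maps"]
                report["stages"]["sdi"] = {"cutoff": res["cutoff"]}
            elif stage == "compare":
                if sdi_maps is None:
                    raise ValueError("compare requires the sdi stage")
                compare_block = _stage_compare(cohort, sdi_maps, config, out)
                report["stages"]["compare"] = {
                    k: v for k, v in compare_block.items() if k not in ("tmap", "mask")
                }
            elif stage == "assoc":
                if config.annotation_dir is None:
                    continue
                if compare_block is None:
                    raise ValueError("assoc requires the compare stage")
                report["stages"]["assoc"] = _stage_assoc(cohort, compare_block, config, out)
            elif stage == "pls":
                if config.expression_path is None:
                    continue
                if compare_block is None:
                    raise ValueError("pls requires the compare stage")
                report["stages"]["pls"] = _stage_pls(cohort, compare_block, config, out)
            elif stage == "classify":
                if sdi_maps is None:
                    raise ValueError("classify requires the sdi stage")
                report["stages"]["classify"] = _stage_classify(cohort, sdi_maps, config, out)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            _write_json(report, out / "report.partial.json")
            raise PipelineError(stage, str(exc)) from exc
    _write_json(report, out / "report.json")
    return report
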