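"""End-to-end pipeline: simulate/ingest -> build -> classify -> metrics -> inference.

`run_full_analysis` wires the whole workflow and writes a deterministic
report bundle (JSON + CSV).  All randomness is derived from the single
config seed through fixed offsets, so identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import graphmetrics, hierarchy, inference, netbuild, simcohort, sparsity_select
from .simcohort import SimConfig

__all__ = ["AnalysisConfig", "run_full_analysis"]

log = logging.getLogger("hierconn")

# fixed seed offsets per stage (all results reproducible from cfg.seed)
_SEED_NULLS = 1_001
_SEED_COMMUNITY = 2_002
_SEED_PERM = 3_003
_SEED_NBS = 4_004
_SEED_SPARSITY = 5_005


@dataclass
class AnalysisConfig:
    sim: SimConfig | None = None
    input_dir: str | None = None  # alternative to sim: cohort.csv + per-scan TSVs
    sparsity: float | str = 0.2  # a fixed density or "select"
    consensus: float = 0.6
    fraction: float = 0.15
    n_nulls: int = 1000  # rewiring nulls per scan for phi_norm
    n_perm_group: int = 10_000
    n_perm_nbs: int = 5000
    n_label_perms: int = 1000
    n_restarts: int = 100
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.sim is None and self.input_dir is None:
            raise ValueError("either sim or input_dir is required")
        for name in ("n_nulls", "n_perm_group", "n_perm_nbs", "n_restarts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _json_default(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not serializable: {type(obj)}")


def _scan_groups(cohort: pd.DataFrame) -> dict[str, list[str]]:
    return {
        "control": list(cohort.loc[cohort.group == "control", "subject_id"]),
        "off": list(cohort.loc[cohort.condition == "off", "subject_id"]),
        "on": list(cohort.loc[cohort.condition == "on", "subject_id"]),
    }


def _covariate_matrix(cohort: pd.DataFrame, scan_ids: list[str], names: list[str]) -> np.ndarray | None:
    if not names:
        return None
    sub = cohort.set_index("subject_id").loc[scan_ids, names]
    return sub.to_numpy(dtype=float)


def run_full_analysis(cfg: AnalysisConfig) -> dict[str, Any]:
    """Run the complete hierarchical connectome analysis; returns the report.

    Stages (in order): per-scan FC and proportional thresholding; control
    consensus group average; rich/feeder/peripheral classification plus
    diverse club; per-scan normalized rich-club curves and subnetwork
    reports; the contrast set {control vs OFF, control vs ON, OFF vs ON
    paired} for every metric with FDR within metric families; rich-club
    presence tests per group; NBS within the rich-club and feeder edge sets;
    degree coupling and change-rate partial correlations with their
    Bonferroni families.  If ``cfg.outdir`` is set the bundle is also
    written to disk.
    """
    report: dict[str, Any] = {"seed": cfg.seed}
    outdir = Path(cfg.outdir) if cfg.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    @contextmanager
    def stage(name: str):
        """Abort with a stage-named message; outputs written so far are kept."""
        t0 = time.perf_counter()
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        log.info("stage '%s' done in %.2fs", name, time.perf_counter() - t0)

    # -- stage 1: cohort ---------------------------------------------------
    with stage("cohort"):
        if cfg.sim is not None:
            panel, cohort, truth = simcohort.simulate_cohort(cfg.sim)
            report["cohort_source"] = "simulated"
        else:
            cohort = simcohort.load_cohort_table(Path(cfg.input_dir) / "cohort.csv")
            panel = simcohort.load_panel(cfg.input_dir, cohort)
            truth = None
            report["cohort_source"] = str(cfg.input_dir)
        groups = _scan_groups(cohort)
        if outdir is not None:
            cohort.to_csv(outdir / "cohort.csv", index=False)
    log.info("cohort: %d controls, %d off, %d on scans",
             len(groups["control"]), len(groups["off"]), len(groups["on"]))

    # -- stage 2: connectomes ---------------------------------------------
    with stage("connectomes"):
        fcs = {sid: netbuild.compute_fc(panel.data[sid], panel.node_labels)
               for sid in panel.subject_ids}
        if cfg.sparsity == "select":
            grid = sparsity_select.default_grid()
            disc = groups["control"] + groups["off"]
            y = np.array([0] * len(groups["control"]) + [1] * len(groups["off"]))
            nets_by_s = {
                float(s): [netbuild.threshold_proportional(fcs[sid], float(s)) for sid in disc]
                for s in grid
            }
            sel = sparsity_select.select_sparsity(
                nets_by_s, y, n_label_perms=cfg.n_label_perms, seed=cfg.seed + _SEED_SPARSITY
            )
            sparsity = sel.selected_sparsity
            report["sparsity_selection"] = dataclasses.asdict(sel)
        else:
            sparsity = float(cfg.sparsity)
        report["sparsity"] = sparsity
        nets = {sid: netbuild.threshold_proportional(fcs[sid], sparsity)
                for sid in panel.subject_ids}

    # -- stage 3: classification from the control group average -----------
    with stage("classification"):
        control_avg = netbuild.group_average(
            [nets[sid] for sid in groups["control"]], cfg.consensus
        )
        cls = hierarchy.classify_nodes(control_avg, cfg.fraction)
        club, partition, pcoef = hierarchy.diverse_club(
            control_avg, cfg.fraction, n_restarts=cfg.n_restarts, seed=cfg.seed + _SEED_COMMUNITY
        )
        report["classification"] = {
            "rich": cls.rich.tolist(),
            "feeder": cls.feeder.tolist(),
            "peripheral": cls.peripheral.tolist(),
            "diverse_club": club.tolist(),
            "modularity_q": partition.q,
            "n_communities": partition.n_communities,
        }
        if truth is not None:
            report["planted_rich_recovered"] = (
                sorted(map(int, truth.rich_nodes)) == cls.rich.tolist()
            )
        if outdir is not None:
            (outdir / "classification.json").write_text(
                json.dumps(report["classification"], sort_keys=True, indent=1,
                           default=_json_default)
            )

    # -- stage 4: per-scan metrics -----------------------------------------
    with stage("subnetwork_metrics"):
        reports = {sid: hierarchy.subnetwork_metrics(nets[sid], cls) for sid in panel.subject_ids}
        frame = hierarchy.reports_to_frame(reports)
        div = {sid: hierarchy.diverse_subnetwork_metrics(nets[sid], club)
               for sid in panel.subject_ids}
        frame["strength_diverse"] = [div[sid][0] for sid in frame.index]
        frame["eff_diverse"] = [div[sid][1] for sid in frame.index]
        if outdir is not None:
            frame.round(10).to_csv(outdir / "subnetwork_reports.csv")

    with stage("rich_club_curves"):
        curves = {
            sid: graphmetrics.rich_club_normalized(
                nets[sid], n_nulls=cfg.n_nulls, seed=cfg.seed + _SEED_NULLS + i
            )
            for i, sid in enumerate(panel.subject_ids)
        }

    # -- stage 5: rich-club presence per arm --------------------------------
    with stage("rich_club_presence"):
        kmax = max(c.k.size for c in curves.values())
        presence = {}
        for arm, ids in groups.items():
            mat = np.full((len(ids), kmax), np.nan)
            for r, sid in enumerate(ids):
                mat[r, : curves[sid].phi_norm.size] = curves[sid].phi_norm
            presence[arm] = inference.rich_club_presence(mat, np.arange(1, kmax + 1))
        report["rich_club_presence"] = {
            arm: {kk: vv for kk, vv in res.items()} for arm, res in presence.items()
        }

    # -- stage 6: group contrasts -------------------------------------------
    with stage("group_contrasts"):
        metrics = list(hierarchy.SubnetworkReport.FIELDS) + ["strength_diverse", "eff_diverse"]
        families = {
            "strength": [m for m in metrics if m.startswith("strength")],
            "efficiency": [m for m in metrics if m.startswith("eff")],
            "degree_sum": [m for m in metrics if m.startswith("degsum")],
            "interaction": [m for m in metrics if m.startswith("interaction")],
        }
        contrasts: dict[str, dict[str, Any]] = {}
        off_map = cohort.loc[cohort.condition == "off"].set_index("pair_id")["subject_id"]
        on_map = cohort.loc[cohort.condition == "on"].set_index("pair_id")["subject_id"]
        pair_ids = sorted(set(off_map.index) & set(on_map.index))
        for name, (a, b) in {
            "control_vs_off": ("control", "off"),
            "control_vs_on": ("control", "on"),
        }.items():
            ids = groups[a] + groups[b]
            gl = np.array([0] * len(groups[a]) + [1] * len(groups[b]))
            zc = _covariate_matrix(cohort, ids, cfg.covariates)
            res = {}
            for i, m in enumerate(metrics):
                vals = frame.loc[ids, m].to_numpy()
                res[m] = inference.perm_test_group(
                    vals, gl, zc, n_perm=cfg.n_perm_group, seed=cfg.seed + _SEED_PERM + i,
                    covariate_names=cfg.covariates,
                )
            contrasts[name] = res
        off_ids = [off_map[p] for p in pair_ids]
        on_ids = [on_map[p] for p in pair_ids]
        contrasts["off_vs_on"] = {
            m: inference.paired_compare(frame.loc[off_ids, m].to_numpy(), frame.loc[on_ids, m].to_numpy())
            for m in metrics
        }

        stats_records = []
        for cname, res in contrasts.items():
            for fam, members in families.items():
                pvals = np.array([res[m].p for m in members])
                rej, _ = inference.fdr_bh(pvals)
                for m, r in zip(members, rej):
                    rec = dataclasses.asdict(res[m])
                    rec.update(metric=m, contrast=cname, family=fam, significant_fdr=bool(r))
                    stats_records.append(rec)
        report["contrasts"] = stats_records

    # -- stage 7: NBS within rich and feeder subnetworks --------------------
    with stage("nbs"):
        nbs_out = {}
        for subnet, nodes in (("rich", cls.rich), ("feeder", cls.feeder)):
            if nodes.size < 2:
                continue
            edge_index = [(int(a), int(b)) for ai, a in enumerate(nodes) for b in nodes[ai + 1:]]
            for cname, (a, b) in {
                "control_vs_off": ("control", "off"),
                "control_vs_on": ("control", "on"),
            }.items():
                ids = groups[a] + groups[b]
                gl = np.array([0] * len(groups[a]) + [1] * len(groups[b]))
                zc = _covariate_matrix(cohort, ids, cfg.covariates)
                y = np.array([[nets[sid].weights[e] for e in edge_index] for sid in ids])
                res = inference.nbs(
                    y, gl, edge_index, zc, primary_p=0.05,
                    n_perm=cfg.n_perm_nbs, seed=cfg.seed + _SEED_NBS,
                )
                nbs_out[f"{subnet}:{cname}"] = {
                    "component_sizes": res.component_sizes,
                    "fwe_pvals": res.fwe_pvals,
                    "components": res.components,
                    "n_perm": res.n_perm,
                    "seed": res.seed,
                }
        report["nbs"] = nbs_out

    # -- stage 8: degree coupling and change-rate correlations --------------
    with stage("correlations"):
        # family of 4: peripheral vs rich/feeder degree in OFF, and the
        # change-rate/improvement-rate pairings after medication
        off_frame = frame.loc[off_ids]
        on_frame = frame.loc[on_ids]
        zc_off = _covariate_matrix(cohort, off_ids, cfg.covariates)
        corr4 = {}
        for other in ("degsum_rich", "degsum_feeder"):
            corr4[f"off_degsum_peripheral_vs_{other}"] = inference.partial_correlation(
                off_frame["degsum_peripheral"].to_numpy(), off_frame[other].to_numpy(),
                zc_off, family_size=4, covariate_names=cfg.covariates,
            )
        rates = hierarchy.change_rates(
            off_frame.set_axis(pair_ids), on_frame.set_axis(pair_ids)
        )
        for other in ("degsum_rich", "degsum_feeder"):
            x = rates[("change", "degsum_peripheral")].to_numpy()
            y2 = rates[("improvement", other)].to_numpy()
            ok = np.isfinite(x) & np.isfinite(y2)
            corr4[f"change_peripheral_vs_improvement_{other}"] = inference.partial_correlation(
                x[ok], y2[ok], _covariate_matrix(cohort, list(np.array(off_ids)[ok]), cfg.covariates),
                family_size=4, covariate_names=cfg.covariates,
            )
        report["correlations_family4"] = {k: dataclasses.asdict(v) for k, v in corr4.items()}

        # family of 27 (3 subnetworks x 3 properties x 3 relationships) applies
        # to clinical scores; computed only when the cohort table provides one
        if "clinical_score" in cohort.columns:
            corr27 = {}
            score = cohort.set_index("subject_id").loc[off_ids, "clinical_score"].to_numpy(dtype=float)
            for m in [m for m in metrics if m.split("_")[0] in ("strength", "eff", "degsum")][:9]:
                corr27[f"off_{m}_vs_score"] = dataclasses.asdict(
                    inference.partial_correlation(
                        off_frame[m].to_numpy(), score, zc_off, family_size=27,
                        covariate_names=cfg.covariates,
                    )
                )
            report["correlations_family27"] = corr27
        report["bonferroni_thresholds"] = {
            "family_27": inference.bonferroni_threshold(0.05, 27),
            "family_4": inference.bonferroni_threshold(0.05, 4),
        }

    # -- write bundle --------------------------------------------------------
    if outdir is not None:
        (outdir / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1, default=_json_default)
        )
    report["subnetwork_reports"] = frame
    return report
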