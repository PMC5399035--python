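"""End-to-end orchestration: generate → preprocess → invert → connect → test.

A run is fully determined by its :class:`RunConfig` (single seed; every
stage derives its own stream from it) and leaves behind a directory of
text artifacts: the run manifest, per-group mean/SD connectivity matrices,
the edge-wise statistics table with post-hoc contrasts, RSN comparisons,
score correlations, the hippocampal-volume comparison and the
beamformer-weight leakage check.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (RSNDefinition, effective_samples, hilbert_phase,
                           plv_area, plv_significance, rsn_average)
from .forward import leadfield_matrix
from .group_stats import (Design, compare_scalar_ancova, correlate_scores,
                          edge_stats_table, fdr_bh)
from .preprocessing import (bandpass_fir, enforce_min_epochs,
                            reject_artifact_epochs, scaled_order, scaled_pad)
from .source_reconstruction import (Leadfield, apply_weights,
                                    epoch_covariance, lcmv_weights,
                                    weight_correlation_matrix)
from .spectral import define_band, detect_iaf, power_spectrum
from .synthetic import TOY_RSNS, GroundTruthSpec, default_spec, generate_cohort

log = logging.getLogger("alphasync")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; ``seed`` is mandatory."""

    seed: int
    band_mode: str = "sample-average"       # or "per-subject"
    fir_order: int | None = None            # None: 1800 scaled by rate/1kHz
    pad_samples: int | None = None          # None: 2000 scaled by rate/1kHz
    regularization: float = 0.05
    n_perm: int = 10000
    q: float = 0.05
    min_epochs: int = 15
    amplitude_z_threshold: float = 6.0
    jump_z_threshold: float = 6.0
    iaf_search: tuple[float, float] = (6.0, 13.0)
    t_effective_mode: str = "nominal"       # or "bandwidth" (deflated T)
    posterior_y_max: float = -0.02          # sensors with y below are posterior
    rsn: dict = field(default_factory=lambda: {k: list(v)
                                               for k, v in TOY_RSNS.items()})
    figures: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        errors = validate_config(raw)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        if "iaf_search" in raw:
            raw["iaf_search"] = tuple(raw["iaf_search"])
        return cls(**raw)


def validate_config(raw: dict) -> list[str]:
    """Schema check with precise messages; empty list means valid."""
    errors = []
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    if "seed" not in raw:
        errors.append("seed is required")
    elif not isinstance(raw["seed"], int):
        errors.append("seed must be an integer")
    q = raw.get("q", 0.05)
    if not (isinstance(q, (int, float)) and 0 < q < 1):
        errors.append("q must lie in (0, 1)")
    n_perm = raw.get("n_perm", 10000)
    if not (isinstance(n_perm, int) and n_perm >= 100):
        errors.append("n_perm must be an integer >= 100")
    if raw.get("band_mode", "sample-average") not in ("sample-average",
                                                     "per-subject"):
        errors.append("band_mode must be 'sample-average' or 'per-subject'")
    if raw.get("t_effective_mode", "nominal") not in ("nominal", "bandwidth"):
        errors.append("t_effective_mode must be 'nominal' or 'bandwidth'")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    return errors


def posterior_channels(epochs, y_max: float) -> list[str]:
    """Occipito-parietal sensor subset by the y-coordinate convention."""
    names = np.array(epochs.channel_names)
    mask = epochs.channel_positions[:, 1] <= y_max
    if not mask.any():
        raise ValueError("no posterior channels under the y threshold")
    return names[mask].tolist()


def _edge_names(area_names: list[str]) -> list[str]:
    return [f"{a}|{b}" for i, a in enumerate(area_names)
            for b in area_names[i + 1:]]


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 subjects=None, spec: GroundTruthSpec | None = None,
                 source_positions=None, source_orientations=None,
                 atlas_labels=None) -> dict:
    """Execute the full analysis and write artifacts under ``out_dir``.

    Either pass a generated/loaded cohort (``subjects`` plus the source
    grid used for reconstruction) or a generator ``spec`` (defaults to the
    study-emulating spec seeded from the config).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_master = np.random.SeedSequence(config.seed)
    stat_seed = int(rng_master.generate_state(1)[0] % (2**31))

    if subjects is None:
        if spec is None:
            spec = default_spec(seed=config.seed)
        log.info("generating cohort (%s subjects)",
                 sum(spec.n_subjects_per_group.values()))
        subjects, _report = generate_cohort(spec)
    if spec is not None:
        source_positions = spec.source_positions
        source_orientations = spec.source_orientations
        atlas_labels = spec.atlas_labels
    if source_positions is None or atlas_labels is None:
        raise ValueError("source grid with atlas labels is required")
    labels = np.asarray(atlas_labels)

    # ---- preprocessing: artifact rejection + inclusion rule -------------
    kept_subjects, rejection_rows, excluded = [], [], []
    for s in subjects:
        clean, rej = reject_artifact_epochs(
            s.sensor_epochs, config.amplitude_z_threshold,
            config.jump_z_threshold)
        for _, r in rej.iterrows():
            rejection_rows.append({"subject_id": s.subject_id, **r.to_dict()})
        if not enforce_min_epochs(clean, config.min_epochs):
            excluded.append({"subject_id": s.subject_id,
                             "reason": f"only {clean.n_epochs} clean epochs "
                                       f"(minimum {config.min_epochs})"})
            continue
        kept_subjects.append((s, clean))
    pd.DataFrame(rejection_rows,
                 columns=["subject_id", "epoch", "reason", "statistic"]
                 ).to_csv(out / "rejection_log.csv", index=False)
    if not kept_subjects:
        raise RuntimeError("no subjects survive the minimum-epoch rule")

    # ---- band definition ------------------------------------------------
    iafs = {}
    for s, clean in kept_subjects:
        post = posterior_channels(clean, config.posterior_y_max)
        spectrum = power_spectrum(clean, post)
        iafs[s.subject_id] = detect_iaf(spectrum, config.iaf_search)
    sample_iaf = float(np.mean(list(iafs.values())))
    band = define_band(sample_iaf)
    log.info("sample-average IAF %.2f Hz -> band %.2f-%.2f Hz",
             sample_iaf, band.low_edge, band.high_edge)

    # ---- per-subject inversion + connectivity ---------------------------
    rate = kept_subjects[0][1].rate
    lf_free = leadfield_matrix(source_positions,
                               kept_subjects[0][1].channel_positions,
                               kept_subjects[0][1].channel_orientations,
                               source_orientations=None)
    area_names = sorted(set(labels.tolist()))
    edge_names = _edge_names(area_names)
    conn_rows, leak_rows, rsn_rows = [], [], []
    design_rows = []
    sig_rows = []
    rsn_defs = [RSNDefinition(name, tuple(members))
                for name, members in config.rsn.items()]
    for s, clean in kept_subjects:
        sband = band if config.band_mode == "sample-average" \
            else define_band(iafs[s.subject_id])
        filtered = bandpass_fir(clean, sband, order=config.fir_order,
                                pad_samples=config.pad_samples)
        cov = epoch_covariance(filtered)
        filt = lcmv_weights(Leadfield(lf_free), cov,
                            regularization_fraction=config.regularization)
        src = apply_weights(filt, filtered)
        phases = hilbert_phase(src, pad_samples=config.pad_samples
                               if config.pad_samples is not None
                               else scaled_pad(rate))
        conn = plv_area(phases, labels)
        conn_rows.append(_upper(conn.plv))
        t_eff = phases.T if config.t_effective_mode == "nominal" \
            else effective_samples(phases.T, sband.width, rate)
        sig_rows.append([plv_significance(v, t_eff)
                         for v in _upper(conn.plv)])
        leak = weight_correlation_matrix(filt, labels)
        leak_rows.append(_upper(leak.to_numpy()))
        rsn_rows.append({d.name: rsn_average(conn, d) for d in rsn_defs})
        design_rows.append({"subject_id": s.subject_id, "group": s.group,
                            "age": s.age, **s.scores,
                            "hippocampal_volume": s.hippocampal_volume})

    edges = np.asarray(conn_rows)           # subjects × edges
    leaks = np.asarray(leak_rows)
    covariates = pd.DataFrame(design_rows)
    design = Design(covariates["subject_id"].tolist(),
                    covariates["group"].to_numpy(),
                    covariates["age"].to_numpy())
    groups_arr = covariates["group"].to_numpy()

    # ---- per-link analytic significance (within group, FDR) -------------
    link_sig = []
    pvals = np.asarray(sig_rows)
    for g in dict.fromkeys(groups_arr):
        gp = pvals[groups_arr == g]
        med = np.median(gp, axis=0)
        mask, _ = fdr_bh(med, q=config.q)
        link_sig.append(pd.DataFrame({"group": g, "edge": edge_names,
                                      "median_p": med,
                                      "significant": mask}))
    pd.concat(link_sig).to_csv(out / "link_significance.csv", index=False)

    # ---- group mean / SD matrices ---------------------------------------
    n_areas = len(area_names)
    iu = np.triu_indices(n_areas, k=1)
    for g in dict.fromkeys(groups_arr):
        sub = edges[groups_arr == g]
        for stat, arr in (("mean", sub.mean(0)), ("sd", sub.std(0, ddof=1))):
            m = np.zeros((n_areas, n_areas))
            m[iu] = arr
            m += m.T
            if stat == "mean":
                np.fill_diagonal(m, 1.0)
            pd.DataFrame(m, index=area_names, columns=area_names).to_csv(
                out / f"connectivity_{stat}_{g}.csv")

    # ---- edge-wise permutation ANCOVA + FDR + post-hoc -------------------
    edge_stats, pairwise = edge_stats_table(
        edges, design, edge_names, n_perm=config.n_perm, q=config.q,
        seed=stat_seed)
    edge_stats.to_csv(out / "edge_stats.csv", index=False)
    pairwise.to_csv(out / "pairwise_stats.csv", index=False)

    # ---- RSN comparison ---------------------------------------------------
    rsn_values = pd.DataFrame(rsn_rows)
    rsn_out = []
    for d in rsn_defs:
        res = compare_scalar_ancova(rsn_values[d.name].to_numpy(), design,
                                    n_perm=config.n_perm, seed=stat_seed + 7)
        rsn_out.append({"network": d.name, "F": res["F"],
                        "p_perm": res["p_perm"]})
    pd.DataFrame(rsn_out).to_csv(out / "rsn_stats.csv", index=False)

    # ---- score correlations ----------------------------------------------
    score_cols = [c for c in covariates.columns
                  if c not in ("subject_id", "group", "age")]
    correlations = correlate_scores(edges, edge_names,
                                    covariates[score_cols], q=config.q)
    correlations.to_csv(out / "correlations.csv", index=False)

    # ---- hippocampal volume ----------------------------------------------
    hip = compare_scalar_ancova(
        covariates["hippocampal_volume"].to_numpy(), design,
        n_perm=config.n_perm, seed=stat_seed + 13)
    hip_out = {"F": hip["F"], "p_perm": hip["p_perm"],
               "pairwise": hip["pairwise"].to_dict(orient="records")}
    (out / "hippocampal_volume.json").write_text(json.dumps(hip_out, indent=1))

    # ---- leakage check ----------------------------------------------------
    leak_stats, _ = edge_stats_table(leaks, design, edge_names,
                                     n_perm=config.n_perm, q=config.q,
                                     seed=stat_seed + 23)
    leak_stats.to_csv(out / "leakage_stats.csv", index=False)

    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "sample_average_iaf": sample_iaf,
        "band": {"iaf": band.iaf, "low_edge": band.low_edge,
                 "high_edge": band.high_edge},
        "fir_order": config.fir_order or scaled_order(rate),
        "pad_samples": config.pad_samples or scaled_pad(rate),
        "n_subjects": len(kept_subjects),
        "excluded_subjects": excluded,
        "n_edges": len(edge_names),
        "n_fdr_discoveries": int(edge_stats["fdr_rejected"].sum()),
        "n_leakage_discoveries": int(leak_stats["fdr_rejected"].sum()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    if config.figures:
        _render_figures(out, area_names, groups_arr)

    return {"manifest": manifest, "edge_stats": edge_stats,
            "pairwise": pairwise, "correlations": correlations,
            "rsn_stats": pd.DataFrame(rsn_out), "hippocampal": hip_out,
            "leakage_stats": leak_stats, "band": band,
            "covariates": covariates, "edges": edges,
            "edge_names": edge_names}


def _render_figures(out: Path, area_names: list[str],
                    groups_arr: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for g in dict.fromkeys(groups_arr):
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, stat in zip(axes, ("mean", "sd")):
            m = pd.read_csv(out / f"connectivity_{stat}_{g}.csv", index_col=0)
            im = ax.imshow(m.to_numpy(), cmap="viridis")
            ax.set_title(f"{g} {stat} PLV")
            ax.set_xticks(range(len(area_names)))
            ax.set_xticklabels(area_names, rotation=90, fontsize=6)
            ax.set_yticks(range(len(area_names)))
            ax.set_yticklabels(area_names, fontsize=6)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(out / f"connectivity_{g}.png", dpi=120)
        plt.close(fig)
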