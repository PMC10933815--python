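"""End-to-end orchestration: simulate -> decompose -> netmats -> clusters
-> assoc, as a reproducible run directory with a manifest.

`run_pipeline` executes the stages in order, writing each stage's outputs
as CSV/JSON under the run directory; stages whose outputs already exist are
skipped when ``resume=True``, and downstream stages re-read the cached
files, so deleting any intermediate and resuming reproduces identical
results.  `report` renders summary figures from a completed run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, clusters, io, netmats
from .decompose import (
    bold_amplitude,
    measure_table,
    network_amplitude,
    spatial_regress,
    temporal_synchrony,
)
from .synthcohort import SimConfig, simulate_cohort

__all__ = ["compute_measures", "run_pipeline", "report"]

MEASURES = ("network_amplitude", "temporal_synchrony", "bold_amplitude")


def compute_measures(cohort, bold_method: str = "binary_mean") -> dict:
    """All three S x K measure tables for a simulated cohort.

    Returns a dict keyed by measure name with labelled DataFrames (see
    :func:`rsnamp.decompose.measure_table`).
    """
    cfg = cohort.config
    s, k = cfg.n_subjects, cfg.n_networks
    amp = np.empty((s, k))
    syn = np.empty((s, k))
    bold = np.empty((s, k))
    for i, run in enumerate(cohort.runs):
        amp[i] = network_amplitude(spatial_regress(run, cohort.maps))
        syn[i] = temporal_synchrony(run, cohort.maps)
        bold[i] = bold_amplitude(run, cohort.maps, method=bold_method)
    labels = cohort.maps.network_labels
    return {
        "network_amplitude": measure_table(amp, "network_amplitude", labels),
        "temporal_synchrony": measure_table(syn, "temporal_synchrony", labels),
        "bold_amplitude": measure_table(
            bold, "bold_amplitude", labels, method=bold_method
        ),
    }


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_done(out: Path, files: list[str]) -> bool:
    return all((out / f).exists() for f in files)


def run_pipeline(
    config: SimConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    resume: bool = False,
) -> Path:
    """Run the full synthetic-cohort analysis into ``out_dir``.

    ``config`` is a :class:`SimConfig` or a path to its YAML form; ``seed``
    overrides the config's seed when given.  Returns the run directory.
    """
    if not isinstance(config, SimConfig):
        config = io.config_from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}

    # stage 0: config snapshot
    io.config_to_yaml(config, out / "config.yaml")

    # stage 1: simulate + decompose (runs are held in memory; the measures
    # are the cached artifact, one CSV per measure)
    measure_files = [f"{m}.csv" for m in MEASURES]
    stage_files = measure_files + ["group_maps.csv", "summary_fc.csv",
                                   "truth_synchrony.csv", "truth_voxel_sd.csv"]
    if not (resume and _stage_done(out, stage_files)):
        t = time.time()
        cohort = simulate_cohort(config)
        io.save_group_maps_csv(cohort.maps, out / "group_maps.csv")
        labels = cohort.maps.network_labels
        amp = np.empty((config.n_subjects, config.n_networks))
        syn = np.empty_like(amp)
        bold = np.empty_like(amp)
        sfc_rows = []
        for i, run in enumerate(cohort.runs):
            ts = spatial_regress(run, cohort.maps)
            amp[i] = network_amplitude(ts)
            syn[i] = temporal_synchrony(run, cohort.maps)
            bold[i] = bold_amplitude(run, cohort.maps)
            sfc = netmats.summary_fc(netmats.partial_correlation(ts))
            frame = sfc.as_frame()
            frame.insert(0, "subject", i)
            sfc_rows.append(frame)
        for name, values in zip(MEASURES, (amp, syn, bold)):
            io.save_measure_table(
                measure_table(values, name, labels), out / f"{name}.csv"
            )
        pd.concat(sfc_rows, ignore_index=True).to_csv(
            out / "summary_fc.csv", index=False
        )
        pd.DataFrame(cohort.truth.true_synchrony, columns=labels).to_csv(
            out / "truth_synchrony.csv", index=False
        )
        pd.DataFrame(cohort.truth.true_voxel_sd_scale, columns=labels).to_csv(
            out / "truth_voxel_sd.csv", index=False
        )
        if cohort.phenotypes is not None:
            cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False,
                                     na_rep="NA")
            cohort.confounds.to_csv(out / "confounds.csv", index=False)
        timings["simulate_decompose"] = time.time() - t

    measures = {m: io.load_measure_table(out / f"{m}.csv") for m in MEASURES}
    labels = list(measures["network_amplitude"].columns)

    # stage 2: clustering of amplitude covariation + cluster amplitudes
    if not (resume and _stage_done(out, ["covariation.csv", "linkage.csv",
                                         "assignment.csv", "cluster_amplitude.csv"])):
        t = time.time()
        cov = clusters.amplitude_covariation(measures["network_amplitude"])
        cr = clusters.ward_cluster(cov, n_clusters=2, network_labels=labels)
        io.save_netmat(cov, labels, out / "covariation.csv")
        io.save_linkage(cr.linkage, out / "linkage.csv")
        pd.DataFrame({"network": labels, "cluster": cr.assignment}).to_csv(
            out / "assignment.csv", index=False
        )
        clusters.cluster_amplitude(measures["network_amplitude"], cr).to_csv(
            out / "cluster_amplitude.csv", index=False
        )
        timings["clusters"] = time.time() - t

    # stage 3: amplitude-FC correlations across subjects
    if not (resume and _stage_done(out, ["amp_fc_across.csv"])):
        t = time.time()
        sfc_long = pd.read_csv(out / "summary_fc.csv")
        sfc_list = []
        for _, grp in sfc_long.groupby("subject", sort=True):
            grp = grp.set_index("network").loc[labels]
            sfc_list.append(
                netmats.SummaryFC(
                    absolute=grp["absolute"].to_numpy(),
                    positive=grp["positive"].to_numpy(),
                    negative=grp["negative"].to_numpy(),
                    network_labels=labels,
                )
            )
        netmats.across_subject_amp_fc(
            measures["network_amplitude"], sfc_list
        ).to_csv(out / "amp_fc_across.csv", index=False)
        timings["netmats"] = time.time() - t

    # stage 4: triplet correlations and (if phenotypes exist) associations
    stage4_files = ["triplet.csv"]
    if (out / "phenotypes.csv").exists():
        stage4_files.append("associations.csv")
    if not (resume and _stage_done(out, stage4_files)):
        t = time.time()
        assoc.triplet_correlations(
            measures["network_amplitude"],
            measures["temporal_synchrony"],
            measures["bold_amplitude"],
        ).to_csv(out / "triplet.csv", index=False)
        if (out / "phenotypes.csv").exists():
            pt = pd.read_csv(out / "phenotypes.csv", na_values=["NA", ""])
            clus = pd.read_csv(out / "cluster_amplitude.csv")
            if (out / "confounds.csv").exists():
                conf = pd.read_csv(out / "confounds.csv")
                if conf.shape[1]:
                    clus = assoc.deconfound(clus, conf)
                    pt = assoc.deconfound(pt, conf)
            assoc.mass_correlate(clus, pt).to_csv(
                out / "associations.csv", index=False
            )
        timings["assoc"] = time.time() - t

    manifest = {
        "seed": config.seed,
        "config": "config.yaml",
        "stages": sorted(p.name for p in out.glob("*.csv")),
        "digests": {p.name: _digest(p) for p in sorted(out.glob("*.csv"))},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir: str | Path, fig_dir: str | Path | None = None) -> list[Path]:
    """Render summary figures from a completed run directory.

    Produces: the covariation heatmap in dendrogram order, a bar panel of
    across-subject amplitude-FC correlations, the triplet-correlation panel,
    and (when associations exist) a Manhattan-style -log10 p profile.
    Returns the list of written figure paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    figs = Path(fig_dir) if fig_dir else run / "figures"
    figs.mkdir(parents=True, exist_ok=True)
    written = []

    needed = ["covariation.csv", "linkage.csv", "amp_fc_across.csv", "triplet.csv"]
    missing = [f for f in needed if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"run {run} is missing stage outputs: {missing}")

    cov = io.load_netmat(run / "covariation.csv")
    linkage = pd.read_csv(run / "linkage.csv").to_numpy()
    from scipy.cluster import hierarchy

    order = hierarchy.leaves_list(linkage)
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(7, 8), height_ratios=[1, 3], constrained_layout=True
    )
    hierarchy.dendrogram(linkage, ax=ax_d, labels=list(cov.columns),
                         color_threshold=None)
    ax_d.set_ylabel("merge height")
    im = ax_h.imshow(cov.to_numpy()[np.ix_(order, order)], vmin=-1, vmax=1,
                     cmap="RdBu_r")
    ax_h.set_xticks(range(len(order)), [cov.columns[i] for i in order],
                    rotation=90)
    ax_h.set_yticks(range(len(order)), [cov.columns[i] for i in order])
    fig.colorbar(im, ax=ax_h, label="across-subject r")
    path = figs / "covariation.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    across = pd.read_csv(run / "amp_fc_across.csv")
    fig, ax = plt.subplots(figsize=(8, 4), constrained_layout=True)
    for i, (fc_type, grp) in enumerate(across.groupby("fc_type")):
        ax.bar(
            np.arange(len(grp)) + 0.25 * i, grp["r"], width=0.25, label=fc_type
        )
    ax.set_xticks(range(across["network"].nunique()),
                  across["network"].unique(), rotation=90)
    ax.set_ylabel("across-subject r (amplitude vs FC)")
    ax.legend()
    path = figs / "amp_fc.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    trip = pd.read_csv(run / "triplet.csv")
    fig, ax = plt.subplots(figsize=(8, 4), constrained_layout=True)
    x = np.arange(len(trip))
    ax.bar(x - 0.15, trip["r_amp_syn"], width=0.3, label="amplitude vs synchrony")
    ax.bar(x + 0.15, trip["r_amp_bold"], width=0.3, label="amplitude vs BOLD amp")
    ax.set_xticks(x, trip["network"], rotation=90)
    ax.set_ylabel("across-subject r")
    ax.legend()
    path = figs / "triplet.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if (run / "associations.csv").exists():
        table = pd.read_csv(run / "associations.csv")
        fig, ax = plt.subplots(figsize=(8, 4), constrained_layout=True)
        if table.empty:
            ax.text(0.5, 0.5, "no variables pass filters",
                    ha="center", va="center")
        else:
            for m_name, grp in table.groupby("measure"):
                ax.scatter(range(len(grp)), grp["neg_log10_p"], label=m_name, s=12)
            ax.set_ylabel("-log10 p")
            ax.set_xlabel("variable")
            ax.legend()
        path = figs / "associations.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    return written
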