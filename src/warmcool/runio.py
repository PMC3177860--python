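"""End-to-end runs: configuration, file formats, and reports.

`run_wcs_analysis` chains colorimetry -> categorization -> SVM selection on
a chip set (synthetic by default, or loaded from a reflectance CSV plus a
counts TSV).  `run_imaging_analysis` chains registration -> activation maps
-> patches -> clustering -> statistics on one or more imaging experiments
(synthetic by default, or loaded from TIFF stacks plus a manifest).  Both
write a JSON report with the resolved configuration; reports contain no
timestamps, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import categorization as cat
from . import imaging as im
from . import svm as sv
from . import synthetic as syn
from .colorimetry import Spectrum, spectrum_to_opponent
from .config import defaults

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_wcs_analysis",
    "run_imaging_analysis",
    "write_experiment",
    "read_experiment",
    "read_reflectance_csv",
    "write_reflectance_csv",
]


@dataclass
class RunConfig:
    """Resolved parameters for a reproducible run.

    Every stochastic stage derives its seed from ``seed``; the config
    round-trips losslessly through YAML.
    """

    seed: int = 0
    outdir: str = "warmcool_out"
    # chip stage
    n_hues: int = 40
    n_values: int = 8
    trials_per_chip: int = 100
    beta: float = 60.0
    features: Literal["opponent", "cone"] = "opponent"
    variant: Literal["a", "b"] = "b"
    folds: int = 0                    # 0 = leave-one-out
    cost: float = 1.0
    reflectance_csv: str | None = None
    counts_tsv: str | None = None
    reference_chip: str | None = None
    # imaging stage
    n_experiments: int = 1
    imaging: dict = field(default_factory=dict)   # ImagingConfig overrides
    imaging_dirs: list[str] = field(default_factory=list)
    map_method: Literal["svm", "conventional"] = "svm"
    min_colors: int = 5
    connectivity: int = 8
    max_shift: int = 3
    anchor_color: str = "B"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


# ---------------------------------------------------------------------------
# Chip-set file formats
# ---------------------------------------------------------------------------

def write_reflectance_csv(chipset: syn.ChipSet, path) -> None:
    """Reflectance CSV: first column wavelength (nm), one column per chip."""
    df = pd.DataFrame(
        chipset.spectra.T, columns=chipset.chips["chip_id"].tolist()
    )
    df.insert(0, "wavelength", chipset.wavelengths)
    df.to_csv(path, index=False)


def read_reflectance_csv(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read (wavelengths, chip_ids, spectra[n_chips, n_wl]) from the CSV."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a wavelength column plus chip columns")
    wavelengths = df.iloc[:, 0].to_numpy(dtype=float)
    ids = list(df.columns[1:])
    return wavelengths, ids, df.iloc[:, 1:].to_numpy(dtype=float).T


def _chip_table_from_files(cfg: RunConfig) -> pd.DataFrame:
    wavelengths, ids, spectra = read_reflectance_csv(cfg.reflectance_csv)
    counts = cat.read_counts_tsv(cfg.counts_tsv)
    ref_id = cfg.reference_chip
    if ref_id is None or ref_id not in ids:
        raise ValueError("reference_chip must name a column of the reflectance CSV")
    ref = Spectrum(wavelengths, spectra[ids.index(ref_id)])
    rows = []
    for cid, refl in zip(ids, spectra):
        c, o = spectrum_to_opponent(Spectrum(wavelengths, refl), ref)
        rows.append({"chip_id": cid, "C_L": c.C_L, "C_M": c.C_M, "C_S": c.C_S,
                     "R_LM": o.R_LM, "R_Y": o.R_Y})
    table = pd.DataFrame(rows).merge(counts, on="chip_id", how="inner")
    if table.empty:
        raise ValueError("no chips shared between reflectance CSV and counts TSV")
    return table


def run_wcs_analysis(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Chip table, quadrant concordance, SVM classifier, and criterion table."""
    if (config.reflectance_csv is None) != (config.counts_tsv is None):
        raise ValueError("provide both reflectance_csv and counts_tsv, or neither")
    if config.reflectance_csv:
        table = _chip_table_from_files(config)
    else:
        chipset = syn.generate_chip_set(syn.ChipSetConfig(
            n_hues=config.n_hues, n_values=config.n_values,
            trials_per_chip=config.trials_per_chip, beta=config.beta,
            seed=config.seed,
        ))
        # the flat-spectrum reference gray is not a categorized chip
        table = chipset.chips[~chipset.chips["is_reference"]].reset_index(drop=True)

    table = cat.categorize_chips(table)
    q_rlm = cat.quadrant_fraction(list(zip(table["I_wc"], table["R_LM"])))
    q_ry = cat.quadrant_fraction(list(zip(table["I_wc"], table["R_Y"])))

    labeled = table[table["I_wc"] != 0]
    dropped = len(table) - len(labeled)
    if dropped:
        logger.info("dropping %d chips with I_wc == 0 from SVM training", dropped)
    if config.features == "opponent":
        names = ("R_LM", "R_Y")
    elif config.features == "cone":
        names = ("C_L", "C_M", "C_S")
    else:
        raise ValueError("features must be 'opponent' or 'cone'")
    ts = sv.TrainingSet(
        labeled[list(names)].to_numpy(),
        np.where(labeled["I_wc"] > 0, 1, -1),
        names,
    )
    clf = sv.train_linear_svm(ts, config.cost)
    n_folds = config.folds if config.folds >= 2 else ts.n_samples
    accuracy = sv.cross_validate(ts, n_folds, config.cost, seed=config.seed)
    w2 = sv.weight_importance(clf)
    selection = sv.select_variables(ts, config.variant, config.cost)

    report: dict = {
        "config": asdict(config),
        "n_chips": int(len(table)),
        "quadrant_rlm": {"concordant": q_rlm.n_concordant, "total": q_rlm.n_total,
                         "fraction": q_rlm.fraction},
        "quadrant_ry": {"concordant": q_ry.n_concordant, "total": q_ry.n_total,
                        "fraction": q_ry.fraction},
        "cv_accuracy": accuracy,
        "n_folds": int(n_folds),
        "hyperplane": {"W": clf.W, "b": clf.b,
                       "axis0_intercept": (-clf.b / clf.W[0] if clf.W[0] != 0 else None)},
        "w2": w2.to_dict(),
        "criterion_table": selection.to_dict(orient="records"),
    }
    if config.features == "opponent":
        sds = labeled[list(names)].std(ddof=0).to_numpy()
        report["border_angle_deg"] = sv.border_angle(clf, axis_index=1, axis_scales=sds)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cat.write_chip_table(table, out / "chips.tsv")
        config.to_yaml(out / "config.yaml")
        (out / "wcs_report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return report


# ---------------------------------------------------------------------------
# Imaging file formats
# ---------------------------------------------------------------------------

def write_experiment(exp: im.ImagingExperiment, directory) -> None:
    """One multi-frame TIFF per trial, plus manifest.tsv and stimuli.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(exp.trials):
        fname = f"trial_{i:04d}.tif"
        tifffile.imwrite(d / fname, t.frames.astype(np.float32))
        rows.append({"trial_id": i, "block": t.block, "stimulus": t.stimulus,
                     "n_frames": t.frames.shape[0], "n_pre": t.n_pre,
                     "filename": fname})
    pd.DataFrame(rows).to_csv(d / "manifest.tsv", sep="\t", index=False)
    exp.stimulus_table.to_csv(d / "stimuli.tsv", sep="\t", index=False)


def read_experiment(directory) -> im.ImagingExperiment:
    """Read an experiment written by :func:`write_experiment`."""
    d = Path(directory)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t")
    stim = pd.read_csv(d / "stimuli.tsv", sep="\t")
    for block, grp in manifest.groupby("block"):
        if im.CONTROL_LABEL not in set(grp["stimulus"]):
            raise ValueError(f"manifest block {block} lacks a control trial")
    trials = []
    for _, row in manifest.iterrows():
        frames = tifffile.imread(d / row["filename"])
        if frames.shape[0] != row["n_frames"]:
            raise ValueError(
                f"{row['filename']}: expected {row['n_frames']} frames, "
                f"got {frames.shape[0]}")
        trials.append(im.Trial(stimulus=row["stimulus"], block=int(row["block"]),
                               frames=frames, n_pre=int(row["n_pre"])))
    return im.ImagingExperiment(trials=trials, stimulus_table=stim)


def _derived_seed(seed: int, i: int) -> int:
    return (seed * 100003 + 7919 * i) % (2**31 - 1)


def run_imaging_analysis(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Analyze one or more experiments and pool the patch statistics."""
    experiments: list[im.ImagingExperiment] = []
    if config.imaging_dirs:
        for d in config.imaging_dirs:
            experiments.append(read_experiment(d))
    else:
        for i in range(config.n_experiments):
            # the study mixed pink variants across sessions; alternate them
            overrides = dict(config.imaging)
            overrides.setdefault("pink", "K1" if i % 2 == 0 else "K2")
            cfg = syn.ImagingConfig(seed=_derived_seed(config.seed, i), **overrides)
            exp, _ = syn.generate_imaging_experiment(cfg)
            experiments.append(exp)

    results = [
        im.analyze_experiment(
            e, map_method=config.map_method, min_colors=config.min_colors,
            connectivity=config.connectivity, max_shift=config.max_shift,
            anchor_color=config.anchor_color,
        )
        for e in experiments
    ]
    pooled = im.pool_patch_assignments(results)
    non_anchor = pooled[pooled["color"] != config.anchor_color]
    pairs_rlm = list(zip(non_anchor["I_pn"], non_anchor["R_LM"]))
    pairs_ry = list(zip(non_anchor["I_pn"], non_anchor["R_Y"]))
    q_rlm = cat.quadrant_fraction(pairs_rlm)
    q_ry = cat.quadrant_fraction(pairs_ry)
    nd_rlm = [n for r in results for n in r.nd_rlm]
    nd_ry = [n for r in results for n in r.nd_ry]
    try:
        t_stat, t_p = im.outlier_t_test(nd_rlm, nd_ry)
    except ValueError as exc:
        logger.warning("outlier t-test unavailable: %s", exc)
        t_stat, t_p = None, None

    report: dict = {
        "config": asdict(config),
        "n_patches": len(nd_rlm),
        "patches_per_experiment": [len(r.nd_rlm) for r in results],
        "threshold_per_experiment": [r.threshold for r in results],
        "ipn_table": pooled.to_dict(orient="records"),
        "quadrant_rlm": {"concordant": q_rlm.n_concordant, "total": q_rlm.n_total,
                         "p": im.quadrant_binomial_test(
                             q_rlm.n_concordant, q_rlm.n_total - q_rlm.n_concordant)},
        "quadrant_ry": {"concordant": q_ry.n_concordant, "total": q_ry.n_total,
                        "p": im.quadrant_binomial_test(
                            q_ry.n_concordant, q_ry.n_total - q_ry.n_concordant)},
        "nd_rlm": nd_rlm,
        "nd_ry": nd_ry,
        "mean_nd_rlm": float(np.mean(nd_rlm)) if nd_rlm else None,
        "mean_nd_ry": float(np.mean(nd_ry)) if nd_ry else None,
        "nd_t": t_stat,
        "nd_p_one_tailed": t_p,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        pooled.to_csv(out / "ipn_summary.tsv", sep="\t", index=False)
        patch_rows = []
        for ei, r in enumerate(results):
            for pi, (patch, named) in enumerate(zip(r.patches, r.assignments)):
                ys, xs = np.nonzero(patch.mask)
                patch_rows.append({
                    "experiment": ei, "patch": pi, "n_pixels": patch.n_pixels,
                    "bbox": [int(ys.min()), int(xs.min()), int(ys.max()), int(xs.max())],
                    "contributing_colors": sorted(patch.contributing_colors),
                    "assignment": named,
                    "nd_rlm": r.nd_rlm[pi], "nd_ry": r.nd_ry[pi],
                })
        (out / "patches.json").write_text(
            json.dumps(_jsonable(patch_rows), indent=2, sort_keys=True) + "\n")
        (out / "imaging_report.json").write_text(
            json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return report
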