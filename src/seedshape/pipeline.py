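"""End-to-end study orchestration: manifest -> descriptors -> averages ->
group statistics -> report bundle.

A *study* starts from a manifest CSV listing one mask image per seed and
view, with species and group metadata and the pixel calibration.  The
pipeline measures every silhouette, builds per-species average
silhouettes, produces a study-level summary (the classic per-descriptor
mean / SD / CV / extremes table), and runs the nonparametric group
comparison twice: on individual silhouettes (all descriptors) and on
average silhouettes (shape descriptors only — area and perimeter are
excluded there because the averaging process randomizes size while the
consensus shape is the quantity of interest).

Group labels always come from the manifest (expert judgment or generator
ground truth); the pipeline never tries to classify seeds into
ornamentation groups itself.

Every stage error is recorded with the offending seed_id and the run
continues; partial results are still written.  Given the same manifest,
config and seeds, all CSV outputs are byte-identical between runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .averaging import AverageSilhouette, align_mask, average_silhouette
from .geometry import compute_descriptors
from .records import SeedRecord
from .silhouette_io import BinaryMask, mask_to_contour, read_manifest, read_mask
from .stats import SeedGroupComparison, SeedGroupComparisonResults, summarize

__all__ = ["StudyConfig", "StudyReport", "run_study",
           "compare_individual_vs_average"]

log = logging.getLogger("seedshape")

#: descriptors compared on average silhouettes (no A/P: size is not a
#: property of a consensus shape)
AVERAGE_DESCRIPTORS = ["AR", "C", "R", "S"]


@dataclass
class StudyConfig:
    """All tunables of a study run; echoed into the report for provenance."""

    alpha: float = 0.05
    adjust: str = "stepdown"          # step-down level adjustment variant
    average_threshold: float = 0.5    # inclusion fraction for the consensus
    normalize_scale: bool = True      # rescale seeds before averaging
    hilum_to_minus_x: bool = True     # lateral-view orientation rule
    smooth_sigma: float = 1.5         # sub-pixel boundary smoothing (px)
    fit_models: bool = False          # fit cardioid models per average
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    """In-memory results of one pipeline run."""

    config: StudyConfig
    descriptors: pd.DataFrame                  # one row per seed x view
    average_descriptors: pd.DataFrame          # one row per species x view
    averages: dict                             # (species, view) -> AverageSilhouette
    summaries: dict                            # view -> summary table
    comparisons: dict                          # view -> results or None
    average_comparisons: dict                  # view -> results or None
    model_fits: pd.DataFrame | None
    errors: list[dict]
    out_dir: Path | None = None


def _load_record(row, base_dir: Path, config: StudyConfig) -> SeedRecord:
    mask = read_mask(base_dir / row["path"],
                     pixel_size=1.0 / float(row["pixels_per_mm"]))
    contour = mask_to_contour(mask, smooth_sigma=config.smooth_sigma)
    return SeedRecord(seed_id=row["seed_id"], species=row["species"],
                      view=row["view"], group=row["group"],
                      contour=contour, mask=mask)


def _comparison(df: pd.DataFrame, descriptors, config: StudyConfig
                ) -> SeedGroupComparisonResults | None:
    groups = [g for g in df["group"].unique() if g != "unknown"]
    if len(groups) < 2:
        return None
    known = df[df["group"] != "unknown"]
    model = SeedGroupComparison(known, descriptors=descriptors,
                                alpha=config.alpha, adjust=config.adjust)
    return model.fit()


def run_study(manifest_path, config: StudyConfig | None = None,
              out_dir=None) -> StudyReport:
    """Run the full analysis for one manifest; optionally write the bundle.

    Raises on an empty or malformed manifest; per-seed failures are
    collected in ``report.errors`` instead of aborting the run.
    """
    config = config or StudyConfig()
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    if manifest.empty:
        raise ValueError("empty manifest")
    base_dir = manifest_path.parent

    records: list[SeedRecord] = []
    errors: list[dict] = []
    for _, row in manifest.iterrows():
        try:
            records.append(_load_record(row, base_dir, config))
        except Exception as exc:  # noqa: BLE001 - reported per seed
            log.warning("seed %s (%s): %s", row["seed_id"], row["view"], exc)
            errors.append({"seed_id": row["seed_id"], "view": row["view"],
                           "error": str(exc)})
    if not records:
        raise ValueError("no silhouette could be extracted from the manifest")

    descriptors = pd.DataFrame([r.as_row() for r in records])

    # per-species average silhouettes
    averages: dict[tuple[str, str], AverageSilhouette] = {}
    avg_rows = []
    for (species, view), group_recs in _groupby(records):
        masks = [r.mask for r in group_recs]
        group = group_recs[0].group
        try:
            if len(masks) == 1:
                aligned = align_mask(masks[0], normalize_scale=False,
                                     hilum_to_minus_x=(
                                         config.hilum_to_minus_x
                                         and view == "lateral"))
                avg = AverageSilhouette(
                    mask=aligned, contour=mask_to_contour(aligned),
                    stack=aligned.grid.astype(float), n_inputs=1,
                    params={"threshold": config.average_threshold,
                            "normalize_scale": config.normalize_scale,
                            "degenerate_single_input": True})
            else:
                avg = average_silhouette(
                    masks, threshold=config.average_threshold,
                    normalize_scale=config.normalize_scale,
                    hilum_to_minus_x=(config.hilum_to_minus_x
                                      and view == "lateral"))
        except Exception as exc:  # noqa: BLE001
            errors.append({"seed_id": f"<average:{species}>", "view": view,
                           "error": str(exc)})
            continue
        averages[(species, view)] = avg
        row = {"species": species, "view": view, "group": group,
               "n_inputs": avg.n_inputs}
        row.update(compute_descriptors(avg.contour).as_dict())
        avg_rows.append(row)
    average_descriptors = pd.DataFrame(avg_rows)

    views = sorted(descriptors["view"].unique())
    summaries = {v: summarize(descriptors, view=v) for v in views}
    comparisons = {
        v: _comparison(descriptors[descriptors["view"] == v], None, config)
        for v in views
    }
    average_comparisons = {
        v: _comparison(
            average_descriptors[average_descriptors["view"] == v],
            [c for c in AVERAGE_DESCRIPTORS
             if c in average_descriptors.columns],
            config)
        for v in views
        if not average_descriptors.empty
    }

    model_fits = None
    if config.fit_models:
        from .models import SeedModelFamily
        fit_rows = []
        for (species, view), avg in averages.items():
            res = SeedModelFamily(avg.contour, family=view).fit(
                seed=config.seed)
            fit_rows.append({"species": species, "view": view,
                             "J": res.j, **res.params})
        model_fits = pd.DataFrame(fit_rows)

    report = StudyReport(
        config=config, descriptors=descriptors,
        average_descriptors=average_descriptors, averages=averages,
        summaries=summaries, comparisons=comparisons,
        average_comparisons=average_comparisons,
        model_fits=model_fits, errors=errors,
    )
    if out_dir is not None:
        _write_bundle(report, Path(out_dir))
    return report


def _groupby(records: list[SeedRecord]):
    keys = sorted({(r.species, r.view) for r in records})
    for key in keys:
        yield key, [r for r in records
                    if (r.species, r.view) == key]


def _write_bundle(report: StudyReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    report.out_dir = out
    report.descriptors.to_csv(out / "descriptors.csv", index=False)
    report.average_descriptors.to_csv(out / "average_descriptors.csv",
                                      index=False)
    (out / "averages").mkdir(exist_ok=True)
    for (species, view), avg in report.averages.items():
        avg.save(out / "averages" / f"{species}_{view}")
    index = {"config": report.config.to_dict(), "errors": report.errors,
             "views": {}}
    for view, summary in report.summaries.items():
        summary.to_csv(out / f"summary_{view}.csv")
        entry = {"summary": f"summary_{view}.csv"}
        comp = report.comparisons.get(view)
        if comp is not None:
            comp.table().to_csv(out / f"comparison_{view}.csv")
            comp.tidy().to_csv(out / f"comparison_{view}_tidy.csv", index=False)
            entry["comparison"] = comp.to_json_dict()
        acomp = report.average_comparisons.get(view)
        if acomp is not None:
            acomp.table().to_csv(out / f"comparison_average_{view}.csv")
            entry["comparison_average"] = acomp.to_json_dict()
        index["views"][view] = entry
    if report.model_fits is not None:
        report.model_fits.to_csv(out / "model_fits.csv", index=False)
    (out / "report.json").write_text(json.dumps(index, indent=1))


def compare_individual_vs_average(report: StudyReport) -> pd.DataFrame:
    """Per-group CV reduction from individual to average silhouettes.

    For each view, group and shape descriptor: the CV across individual
    seeds versus the CV across the species' average silhouettes, their
    ratio (``cv_average / cv_individual``; < 1 means the averaging
    collapsed variation), and the letter assigned in each analysis.
    """
    ind, avg = report.descriptors, report.average_descriptors
    if ind.empty or avg.empty:
        raise ValueError("report lacks individual or average descriptor tables")
    if set(ind["species"]) != set(avg["species"]):
        raise ValueError("species sets differ between individual and "
                         "average tables")
    rows = []
    for view in sorted(ind["view"].unique()):
        i_v = ind[ind["view"] == view]
        a_v = avg[avg["view"] == view]
        comp = report.comparisons.get(view)
        acomp = report.average_comparisons.get(view)
        for group, i_g in i_v.groupby("group"):
            a_g = a_v[a_v["group"] == group]
            for c in AVERAGE_DESCRIPTORS:
                cv_i = (np.std(i_g[c], ddof=1) / np.mean(i_g[c]) * 100
                        if len(i_g) > 1 else 0.0)
                cv_a = (np.std(a_g[c], ddof=1) / np.mean(a_g[c]) * 100
                        if len(a_g) > 1 else 0.0)
                rows.append({
                    "view": view, "group": group, "descriptor": c,
                    "cv_individual": cv_i, "cv_average": cv_a,
                    "cv_ratio": cv_a / cv_i if cv_i > 0 else np.nan,
                    "letters_individual":
                        comp.letters(c).get(group, "") if comp else "",
                    "letters_average":
                        acomp.letters(c).get(group, "") if acomp else "",
                })
    return pd.DataFrame(rows)
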