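"""Experiment drivers, result tables, plots and standard-format adapters.

The two end-to-end drivers replicate the study design: generate a geometry
family, emulate a planned dose per case and modality, compute overlap
features and dose-volume metrics, then run the correlation sweep and the
COPP-vs-POPP comparison.  Everything a run writes (per-case table, summary
table in the layout of the published metric tables, sweep table, manifest)
is reproducible byte-for-byte from the configuration and seed alone.

External data enter through DICOM-RT: RTSTRUCT contours are rasterized
slice-wise onto the RTDOSE grid with the voxel-centre even-odd rule, and
dose values are scaled into Gy by the file's dose-grid scaling.  Synthetic
volumes can be exported as NRRD for inspection in standard viewers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dose_engine import (
    DoseGrid,
    DoseModelParams,
    PlanningProtocol,
    check_plan_goals,
    preset,
    signed_distance_field,
    simulate_plan_dose,
)
from .grid_geometry import StructureMask, VoxelGrid
from .phantom_cases import (
    GeometryCase,
    default_grid,
    generate_simulation1_cases,
    generate_simulation2_cases,
)
from .plan_metrics import overlap_features, plan_quality, volume_at_dose_direct
from .regression_stats import (
    CorrelationSweep,
    compare_correlations,
    significant_ranges,
    sweep_correlations,
    threshold_dose,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "StructureLookupError",
    "IncompatibleFrameError",
    "evaluate_cohort",
    "summarize_cohort",
    "run_experiment",
    "write_results_table",
    "read_rt_inputs",
    "save_volume_nrrd",
    "case_manifest",
]

REPORTED_METRICS = ("dmean", "v70gy", "v60gy", "v37.5gy")


class StructureLookupError(KeyError):
    """A named structure is missing from an RTSTRUCT."""


class IncompatibleFrameError(ValueError):
    """RTSTRUCT and RTDOSE do not share a usable frame of reference."""


@dataclasses.dataclass
class ExperimentConfig:
    """Declarative description of one reproducible experiment run."""

    family: str = "simulation2"            # simulation1 | simulation2
    modality: str = "both"                 # IMRT | VMAT | both
    spacing_mm: float = 2.0
    seed: int = 0
    sweep_range_gy: tuple[float, float] = (20.0, 75.0)
    sweep_step_gy: float = 1.0
    stats_method: str = "dependent-correlation"
    goals_only: bool = False
    output_dir: str | None = None
    write_plots: bool = True

    def modalities(self) -> list[str]:
        if self.modality.lower() == "both":
            return ["IMRT", "VMAT"]
        return [self.modality.upper()]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_range_gy"] = list(d["sweep_range_gy"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "sweep_range_gy" in d:
            d["sweep_range_gy"] = tuple(d["sweep_range_gy"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclasses.dataclass
class ModalityResult:
    """Per-modality artifacts of a run."""

    modality: str
    cases: pd.DataFrame
    summary: pd.DataFrame
    sweeps: dict[str, CorrelationSweep]
    dth_gy: dict[str, float | None]
    goal_pass_count: int


@dataclasses.dataclass
class ExperimentResult:
    config: ExperimentConfig
    geometry: list[GeometryCase]
    per_modality: dict[str, ModalityResult]
    output_files: list[Path] = dataclasses.field(default_factory=list)


def _case_seed(base_seed: int, index: int) -> int:
    # deterministic per-case stream, independent of evaluation order
    return int((base_seed * 1_000_003 + index) % (2**31 - 1))


def _sweep_levels(config: ExperimentConfig) -> np.ndarray:
    lo, hi = config.sweep_range_gy
    return np.arange(lo, hi + 0.5 * config.sweep_step_gy, config.sweep_step_gy)


def evaluate_cohort(
    cases: list[GeometryCase],
    params: DoseModelParams,
    seed: int = 0,
    sweep_levels: np.ndarray | None = None,
    protocol: PlanningProtocol = PlanningProtocol(),
) -> pd.DataFrame:
    """Simulate a plan per case and tabulate features + metrics.

    Returns one row per case with overlap features (COPP/POPP per OAR),
    plan quality (CN, HI, coverage), the reported dose-volume metrics and
    the full V_xGy sweep columns for both OARs.  The PTV signed-distance
    field is cached across cases that share a PTV mask.
    """
    if sweep_levels is None:
        sweep_levels = np.arange(20.0, 75.5, 1.0)
    rows = []
    sdf_cache: dict[int, np.ndarray] = {}
    for i, case in enumerate(cases):
        key = id(case.ptv.occupancy)
        if key not in sdf_cache:
            sdf_cache[key] = signed_distance_field(case.ptv)
        dose = simulate_plan_dose(
            case, params, seed=_case_seed(seed, i), ptv_sdf=sdf_cache[key]
        )
        row: dict = {"case_id": case.case_id, "modality": params.modality}
        for k, v in case.provenance.items():
            if isinstance(v, (int, float, str)):
                row[k] = v
        row.update(
            ptv_cc=case.ptv_cc, rv_cc=case.rv_cc, bv_cc=case.bv_cc,
            rov_cc=case.rov_cc, bov_cc=case.bov_cc,
        )
        for oar_name, oar in (("rectum", case.rectum), ("bladder", case.bladder)):
            feats = overlap_features(oar, case.ptv)
            row[f"{oar_name}_copp"] = feats.copp
            row[f"{oar_name}_popp"] = feats.popp
            doses = np.sort(dose.dose[oar.occupancy])
            row[f"{oar_name}_dmean"] = float(doses.mean())
            row[f"{oar_name}_v37.5gy"] = 100.0 * (
                1.0 - np.searchsorted(doses, 37.5, side="left") / doses.size
            )
            frac = 1.0 - np.searchsorted(doses, sweep_levels, side="left") / doses.size
            for lev, val in zip(sweep_levels, 100.0 * frac):
                row[f"{oar_name}_v{lev:g}gy"] = val
        pq = plan_quality(dose, case.ptv, params.rx_gy)
        row.update(cn=pq.cn, hi=pq.hi, d2_gy=pq.d2_gy, d50_gy=pq.d50_gy, d98_gy=pq.d98_gy)
        row["ptv_coverage_pct"] = volume_at_dose_direct(dose, case.ptv, params.rx_gy)
        row["goals_pass"] = check_plan_goals(dose, case, protocol).passed
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary in the published layout: metric rows, mean +- sd and
    the correlation coefficient of each predictor."""
    from .regression_stats import pearson_r

    rows = []
    for oar in ("rectum", "bladder"):
        copp = table[f"{oar}_copp"].to_numpy()
        popp = table[f"{oar}_popp"].to_numpy()
        for metric in REPORTED_METRICS:
            col = table[f"{oar}_{metric}"].to_numpy()
            rows.append(
                {
                    "oar": oar,
                    "metric": metric,
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                    "r_copp": pearson_r(copp, col),
                    "r_popp": pearson_r(popp, col),
                }
            )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """End-to-end driver: geometry family -> plans -> metrics -> statistics.

    Writes per-case, summary and sweep CSVs (plus optional plots and a
    manifest) under ``config.output_dir`` when set.  Deterministic for a
    fixed config and seed.
    """
    grid = default_grid(config.spacing_mm)
    if config.family == "simulation1":
        cases = generate_simulation1_cases(grid, seed=config.seed)
    elif config.family == "simulation2":
        cases = generate_simulation2_cases(grid, seed=config.seed)
    else:
        raise ValueError(f"unknown case family {config.family!r}")

    levels = _sweep_levels(config)
    result = ExperimentResult(config=config, geometry=cases, per_modality={})
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    for modality in config.modalities():
        params = preset(modality)
        table = evaluate_cohort(cases, params, seed=config.seed, sweep_levels=levels)
        stats_table = table[table["goals_pass"]] if config.goals_only else table
        sweeps: dict[str, CorrelationSweep] = {}
        dth: dict[str, float | None] = {}
        for oar in ("rectum", "bladder"):
            if len(stats_table) >= 3:
                sweep = sweep_correlations(
                    stats_table, oar, config.sweep_range_gy, config.sweep_step_gy
                )
                compare_correlations(sweep, stats_table, method=config.stats_method)
                sweeps[oar] = sweep
                dth[oar] = threshold_dose(sweep)
            else:
                warnings.warn(f"{modality}: too few cases for statistics")
                dth[oar] = None
        summary = summarize_cohort(stats_table)
        mres = ModalityResult(
            modality=modality,
            cases=table,
            summary=summary,
            sweeps=sweeps,
            dth_gy=dth,
            goal_pass_count=int(table["goals_pass"].sum()),
        )
        result.per_modality[modality] = mres
        if outdir is not None:
            result.output_files += write_results_table(mres, outdir)
            if config.write_plots:
                result.output_files += _write_plots(mres, outdir)

    if outdir is not None:
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_cases": len(cases),
            "goal_pass": {m: r.goal_pass_count for m, r in result.per_modality.items()},
            "dth_gy": {m: r.dth_gy for m, r in result.per_modality.items()},
        }
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        result.output_files.append(path)
    return result


def write_results_table(mres: ModalityResult, outdir: Path) -> list[Path]:
    """Tidy per-case CSV + summary CSV + per-OAR sweep CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    p = outdir / f"cases_{mres.modality}.csv"
    mres.cases.to_csv(p, index=False)
    files.append(p)
    p = outdir / f"summary_{mres.modality}.csv"
    mres.summary.to_csv(p, index=False)
    files.append(p)
    for oar, sweep in mres.sweeps.items():
        p = outdir / f"sweep_{mres.modality}_{oar}.csv"
        frame = sweep.to_frame()
        frame.to_csv(p, index=False)
        files.append(p)
    return files


def _write_plots(mres: ModalityResult, outdir: Path) -> list[Path]:
    """Scatter-plus-fit panels and the correlation sweep figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    from .regression_stats import linear_fit

    files = []
    table = mres.cases
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    panels = [
        ("rectum_copp", "rectum_v70gy", "COPP", "rectum V70Gy (%)"),
        ("rectum_popp", "rectum_v70gy", "POPP", "rectum V70Gy (%)"),
        ("rectum_copp", "rectum_v37.5gy", "COPP", "rectum V37.5Gy (%)"),
        ("rectum_popp", "rectum_v37.5gy", "POPP", "rectum V37.5Gy (%)"),
    ]
    for ax, (xcol, ycol, xlab, ylab) in zip(axes.ravel(), panels):
        x = table[xcol].to_numpy()
        y = table[ycol].to_numpy()
        fit = linear_fit(x, y)
        ax.scatter(x, y, s=12, alpha=0.7, edgecolor="none")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, fit.slope * xs + fit.intercept, "k-", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel(ylab)
        ax.set_title(f"R = {fit.pearson_r:.3f}", fontsize=10)
    fig.suptitle(f"{mres.modality}: overlap parameters vs rectum dose-volume metrics")
    fig.tight_layout()
    p = Path(outdir) / f"regression_{mres.modality}.svg"
    fig.savefig(p)
    plt.close(fig)
    files.append(p)

    fig, axes = plt.subplots(1, len(mres.sweeps), figsize=(6 * len(mres.sweeps), 4.5))
    axes = np.atleast_1d(axes)
    for ax, (oar, sweep) in zip(axes, mres.sweeps.items()):
        ax.plot(sweep.dose_levels, sweep.r_copp, label="COPP")
        ax.plot(sweep.dose_levels, sweep.r_popp, label="POPP")
        dth = mres.dth_gy.get(oar)
        if dth is not None:
            ax.axvline(dth, color="gray", ls="--", lw=1, label=f"Dth = {dth:.1f} Gy")
        if sweep.p_values is not None:
            for lo, hi in significant_ranges(sweep.dose_levels, sweep.p_values):
                ax.axvspan(lo, hi, color="orange", alpha=0.12)
        ax.set_xlabel("dose level x (Gy)")
        ax.set_ylabel("Pearson R of V_xGy")
        ax.set_title(f"{mres.modality} {oar}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    p = Path(outdir) / f"sweep_{mres.modality}.svg"
    fig.savefig(p)
    plt.close(fig)
    files.append(p)
    return files


def case_manifest(cases: list[GeometryCase]) -> pd.DataFrame:
    """Case-level manifest: ids, provenance scalars and achieved volumes."""
    rows = []
    for case in cases:
        row = {"case_id": case.case_id}
        for k, v in case.provenance.items():
            if isinstance(v, (int, float, str)):
                row[k] = v
        row.update(
            ptv_cc=case.ptv_cc, rv_cc=case.rv_cc, bv_cc=case.bv_cc,
            rov_cc=case.rov_cc, bov_cc=case.bov_cc,
            rectum_copp=case.rov_cc / case.rv_cc,
            bladder_copp=case.bov_cc / case.bv_cc,
            rectum_popp=case.rov_cc / case.rv_cc * case.ptv_cc / case.rv_cc,
            bladder_popp=case.bov_cc / case.bv_cc * case.ptv_cc / case.bv_cc,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DICOM-RT input
# ---------------------------------------------------------------------------

def _dose_grid_from_rtdose(ds) -> DoseGrid:
    orientation = getattr(ds, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])
    if not np.allclose(np.asarray(orientation, dtype=float), [1, 0, 0, 0, 1, 0]):
        raise IncompatibleFrameError("only axis-aligned RTDOSE orientations are supported")
    ipp = np.asarray(ds.ImagePositionPatient, dtype=float)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = np.diff(offsets)
    if offsets.size < 2 or not np.allclose(dz, dz[0]):
        raise IncompatibleFrameError("RTDOSE frame offsets must be uniform")
    # pixel_array axes are (frame/z, row/y, col/x); package order is (x, y, z)
    dose = np.asarray(ds.pixel_array, dtype=float) * float(ds.DoseGridScaling)
    dose = np.transpose(dose, (2, 1, 0))
    grid = VoxelGrid(
        origin_mm=(ipp[0], ipp[1], ipp[2] + offsets[0]),
        spacing_mm=(col_sp, row_sp, float(dz[0])),
        shape=dose.shape,
    )
    return DoseGrid(grid, dose)


def _rasterize_contours(grid: VoxelGrid, contours: list[np.ndarray], label: str) -> StructureMask:
    from skimage.draw import polygon

    occ = np.zeros(grid.shape, dtype=bool)
    ox, oy, oz = grid.origin_mm
    sx, sy, sz = grid.spacing_mm
    for pts in contours:
        z = pts[:, 2].mean()
        k = int(round((z - oz) / sz))
        if not (0 <= k < grid.shape[2]):
            continue
        cols = (pts[:, 0] - ox) / sx
        rows_ = (pts[:, 1] - oy) / sy
        rr, cc = polygon(rows_, cols, shape=(grid.shape[1], grid.shape[0]))
        # even-odd rule per slice: XOR supports (future) keyhole contours
        occ[cc, rr, k] ^= True
    return StructureMask(grid, occ, label)


def read_rt_inputs(
    rtstruct_path, rtdose_path, structure_names: dict[str, str]
) -> tuple[GeometryCase, DoseGrid]:
    """Load an RTSTRUCT + RTDOSE pair onto a common grid.

    ``structure_names`` maps the roles ``ptv`` / ``rectum`` / ``bladder`` to
    ROI names in the RTSTRUCT.  Contours are rasterized onto the dose grid;
    dose is scaled into Gy.
    """
    import pydicom

    struct = pydicom.dcmread(rtstruct_path)
    dose_ds = pydicom.dcmread(rtdose_path)
    f1 = getattr(struct, "FrameOfReferenceUID", None) or (
        struct.ReferencedFrameOfReferenceSequence[0].FrameOfReferenceUID
        if getattr(struct, "ReferencedFrameOfReferenceSequence", None)
        else None
    )
    f2 = getattr(dose_ds, "FrameOfReferenceUID", None)
    if f1 and f2 and f1 != f2:
        raise IncompatibleFrameError("RTSTRUCT and RTDOSE frames of reference differ")

    dose = _dose_grid_from_rtdose(dose_ds)

    roi_numbers = {roi.ROIName: roi.ROINumber for roi in struct.StructureSetROISequence}
    contours_by_number: dict[int, list[np.ndarray]] = {}
    for rc in struct.ROIContourSequence:
        pts_list = []
        for contour in getattr(rc, "ContourSequence", []):
            data = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            pts_list.append(data)
        contours_by_number[rc.ReferencedROINumber] = pts_list

    masks = {}
    for role in ("ptv", "rectum", "bladder"):
        name = structure_names.get(role)
        if name is None:
            raise StructureLookupError(f"no ROI name given for role {role!r}")
        if name not in roi_numbers:
            raise StructureLookupError(f"ROI {name!r} not found in RTSTRUCT")
        contours = contours_by_number.get(roi_numbers[name], [])
        if not contours:
            raise StructureLookupError(f"ROI {name!r} has no contours")
        masks[role] = _rasterize_contours(dose.grid, contours, name)

    case = GeometryCase.from_structures(
        "external",
        masks["ptv"],
        masks["rectum"],
        masks["bladder"],
        {"case_id": "external", "family": "external",
         "rtstruct": str(rtstruct_path), "rtdose": str(rtdose_path)},
    )
    return case, dose


def save_volume_nrrd(grid: VoxelGrid, array: np.ndarray, path) -> Path:
    """Write a scalar volume as a minimal NRRD (raw little-endian) file."""
    array = np.ascontiguousarray(np.asarray(array), dtype=np.float32)
    if array.shape != grid.shape:
        raise ValueError("array shape must match the grid")
    path = Path(path)
    header = (
        "NRRD0004\n"
        "type: float\n"
        "dimension: 3\n"
        f"sizes: {grid.shape[0]} {grid.shape[1]} {grid.shape[2]}\n"
        "space: left-posterior-superior\n"
        f"space directions: ({grid.spacing_mm[0]},0,0) (0,{grid.spacing_mm[1]},0) "
        f"(0,0,{grid.spacing_mm[2]})\n"
        f"space origin: ({grid.origin_mm[0]},{grid.origin_mm[1]},{grid.origin_mm[2]})\n"
        "endian: little\n"
        "encoding: raw\n\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode())
        fh.write(array.tobytes(order="F"))
    return path
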