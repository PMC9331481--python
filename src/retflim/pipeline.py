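"""End-to-end pipeline: simulate -> phasor -> zones -> ROIs -> channels -> stats.

All randomness flows from one root seed, split deterministically per image
and stage, so a fixed seed reproduces the result bundle bit for bit. Each
simulated image draws its own outer/inner ground-truth means from the
configured between-image spread, which is what makes the downstream paired
comparison a meaningful statistical exercise rather than a tautology.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .channels import learn_selector, phasor_select, shg_mask
from .config import PipelineConfig
from .errors import RetflimError
from .instrument import default_emitters, default_fluorophores
from .io import write_cube, write_label_map, write_mask, write_phasor_field
from .metabolic import analyze_rois, bound_fraction_map, fit_trajectory
from .phasor import calibrate, median_filter_phasor, phasor_center_of_mass, phasor_transform
from .simulate import (
    LAYER_CODES,
    layer_metabolic_profile,
    make_phantom,
    simulate_decay_cube,
    simulate_reference_cube,
)
from .stats import (
    aggregate,
    report_text,
    results_to_frame,
    run_standard_comparisons,
    simulate_image_means,
)
from .viz import render_bound_map, render_overlay
from .zoning import build_zones, make_rois

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    out_dir: Path
    roi_table: pd.DataFrame
    aggregated: pd.DataFrame
    comparisons: list
    fad_table: pd.DataFrame | None = None
    selector_masks: dict = field(default_factory=dict)
    artifacts: list[Path] = field(default_factory=list)


def _stage_seed(root: int, *key: int) -> int:
    """Deterministic per-stage integer seed below 2**31."""
    return int(
        np.random.SeedSequence((root,) + key).generate_state(1)[0] & 0x7FFFFFFF
    )


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                if isinstance(exc, RetflimError):
                    exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            else:
                logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    """Run the full analysis on a batch of simulated retina sections.

    Writes, under ``out_dir``: the last image's label map, decay cubes,
    calibrated phasor fields, structural masks and renderings; the per-ROI
    and aggregated CSV tables over all images; the paired-comparison CSV
    and text report; and a provenance JSON (config hash, seed, versions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    instrument = config.instrument.build()
    fluors = default_fluorophores()
    emitters = default_emitters()
    truth = config.truth
    ana = config.analysis
    artifacts: list[Path] = []

    n_images = config.stats.n_images
    truth_rng = np.random.default_rng(_stage_seed(config.seed, 1))
    nadph_rows = []
    fad_rows = []
    last = {}

    with _stage("simulate+analyze"):
        for i in range(n_images):
            phantom = make_phantom(
                width_um=config.phantom.width_um,
                height_um=config.phantom.height_um,
                pixel_size_um=config.phantom.pixel_size_um,
                vessels=config.phantom.vessels,
                vessel_spacing_um=config.phantom.vessel_spacing_um,
                disc_width_um=config.phantom.disc_width_um,
                section_axis=config.phantom.section_axis,
                seed=_stage_seed(config.seed, 2, i),
            )
            sd_out, sd_in = truth.nadph_between_image_sd
            outer_arr, inner_arr = simulate_image_means(
                1,
                truth.nadph_outer_bound_pct,
                truth.nadph_inner_bound_pct,
                sd_out,
                sd_in,
                shared_sd=truth.nadph_shared_image_sd,
                rng=truth_rng,
            )
            outer_mu = float(np.clip(outer_arr[0], 0, 100))
            inner_mu = float(np.clip(inner_arr[0], 0, 100))
            zones = build_zones(phantom, roi_width_um=ana.roi_width_um)
            rois = make_rois(zones, width_um=ana.roi_width_um)
            ref_cube = simulate_reference_cube(
                instrument,
                ana.calibration_tau_ns,
                photons_per_pixel=1e5,
                seed=_stage_seed(config.seed, 3, i),
            )

            for channel in config.channels:
                if channel == "nadph":
                    grid = layer_metabolic_profile(
                        phantom,
                        outer_mu,
                        inner_mu,
                        jitter_sd=truth.jitter_sd_pct,
                        seed=_stage_seed(config.seed, 4, i),
                    )
                elif channel == "fad":
                    grid = layer_metabolic_profile(
                        phantom,
                        100.0 - truth.fad_outer_free_pct,
                        100.0 - truth.fad_inner_free_pct,
                        jitter_sd=truth.jitter_sd_pct,
                        seed=_stage_seed(config.seed, 5, i),
                    )
                else:
                    grid = None
                cube = simulate_decay_cube(
                    phantom,
                    instrument,
                    channel,
                    photons_per_pixel=ana.photons_per_pixel,
                    ground_truth_pct=grid,
                    fluorophores=fluors,
                    emitters=emitters,
                    seed=_stage_seed(config.seed, 6, i, config.channels.index(channel)),
                )
                fieldp = phasor_transform(cube, harmonic=ana.harmonic)
                fieldp = calibrate(fieldp, ref_cube, ana.calibration_tau_ns)
                if ana.median_filter_window > 1:
                    fieldp = median_filter_phasor(fieldp, ana.median_filter_window)

                if channel == "nadph":
                    results = analyze_rois(
                        fieldp,
                        rois,
                        ana.nadph_free_tau_ns,
                        exclusion_mask=phantom.exclusion_mask,
                    )
                    frame = results_to_frame(results, image_id=i)
                    frame["truth_outer"] = outer_mu
                    frame["truth_inner"] = inner_mu
                    nadph_rows.append(frame)
                elif channel == "fad":
                    results = analyze_rois(
                        fieldp,
                        rois,
                        ana.fad_free_tau_ns,
                        exclusion_mask=phantom.exclusion_mask,
                    )
                    frame = results_to_frame(results, image_id=i)
                    frame["free_pct"] = 100.0 - frame["bound_pct"]
                    fad_rows.append(frame)

                if i == n_images - 1:
                    last.setdefault("fields", {})[channel] = fieldp
                    last.setdefault("cubes", {})[channel] = cube
            if i == n_images - 1:
                last["phantom"] = phantom
                last["zones"] = zones
                last["rois"] = rois

    roi_table = pd.concat(nadph_rows, ignore_index=True)
    fad_table = pd.concat(fad_rows, ignore_index=True) if fad_rows else None

    with _stage("stats"):
        agg = aggregate(roi_table, grouping=config.stats.grouping)
        comparisons = run_standard_comparisons(agg)

    with _stage("channels"):
        selector_masks = _structural_masks(last, ana)

    with _stage("write"):
        phantom = last["phantom"]
        artifacts.append(write_label_map(phantom, out / "label_map.tif"))
        for channel, cube in last["cubes"].items():
            artifacts.append(write_cube(cube, out / f"cube_{channel}.tif"))
        for channel, fieldp in last["fields"].items():
            artifacts.append(
                write_phasor_field(fieldp, out / f"phasor_{channel}.tif")
            )
        for name, mask in selector_masks.items():
            artifacts.append(write_mask(mask, out / f"mask_{name}.tif"))
        if "hb_melanin" in last["fields"]:
            base = last["fields"]["hb_melanin"].intensity
            render_overlay(base, selector_masks, out / "overlay_structures.tif")
            artifacts.append(out / "overlay_structures.tif")
        if "nadph" in last["fields"]:
            fieldp = last["fields"]["nadph"]
            retina = np.isin(
                phantom.labels,
                [LAYER_CODES[k] for k in ("os", "is", "onl", "opl", "inl",
                                          "ipl", "gcl", "rnfl")],
            )
            com = phasor_center_of_mass(fieldp, retina)
            traj = fit_trajectory(
                com, ana.nadph_free_tau_ns, fieldp.angular_frequency
            )
            bmap = bound_fraction_map(fieldp, traj, mask=retina)
            render_bound_map(bmap, out / "bound_map.tif")
            artifacts.append(out / "bound_map.tif")

        roi_table.to_csv(out / "roi_table.csv", index=False)
        artifacts.append(out / "roi_table.csv")
        if fad_table is not None:
            fad_table.to_csv(out / "fad_table.csv", index=False)
            artifacts.append(out / "fad_table.csv")
        agg.to_csv(out / "aggregated.csv")
        artifacts.append(out / "aggregated.csv")
        comp_frame = pd.DataFrame([c.as_dict() for c in comparisons])
        comp_frame.to_csv(out / "comparisons.csv", index=False)
        artifacts.append(out / "comparisons.csv")
        (out / "report.txt").write_text(report_text(comparisons))
        artifacts.append(out / "report.txt")
        provenance = {
            "package": "retflim",
            "version": __version__,
            "seed": config.seed,
            "config": config.model_dump(mode="json"),
            "config_hash": config.content_hash(),
            "versions": _dependency_versions(),
        }
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=1, sort_keys=True)
        )
        artifacts.append(out / "provenance.json")

    return PipelineResult(
        out_dir=out,
        roi_table=roi_table,
        aggregated=agg,
        comparisons=comparisons,
        fad_table=fad_table,
        selector_masks=selector_masks,
        artifacts=artifacts,
    )


def _structural_masks(last: dict, ana) -> dict[str, np.ndarray]:
    """Hemoglobin/melanin/SHG masks on the last image's phasor fields."""
    masks: dict[str, np.ndarray] = {}
    phantom = last["phantom"]
    fields = last.get("fields", {})
    if "hb_melanin" in fields:
        fieldp = fields["hb_melanin"]
        vessel = phantom.labels == LAYER_CODES["vessel"]
        if vessel.any():
            lab, n = ndimage.label(vessel)
            seed = lab == 1  # one vessel as the user-drawn seed ROI
            sel = learn_selector(fieldp, seed, name="hemoglobin")
            sel = type(sel)(
                reference=sel.reference,
                radius=max(sel.radius, ana.selector_radius),
                channel=sel.channel,
                name=sel.name,
            )
            masks["hemoglobin"] = phasor_select(
                fieldp, sel, intensity_floor=ana.intensity_floor
            )
        rpe = phantom.labels == LAYER_CODES["rpe"]
        if rpe.any():
            sel = learn_selector(fieldp, rpe, name="melanin")
            sel = type(sel)(
                reference=sel.reference,
                radius=max(sel.radius, ana.selector_radius),
                channel=sel.channel,
                name=sel.name,
            )
            masks["melanin"] = phasor_select(
                fieldp, sel, intensity_floor=ana.intensity_floor
            )
    if "shg" in fields:
        masks["shg"] = shg_mask(
            fields["shg"], radius=ana.shg_radius, intensity_floor=ana.intensity_floor
        )
    return masks


def _dependency_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy
    import tifffile

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "tifffile": tifffile.__version__,
    }
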