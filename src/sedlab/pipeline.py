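"""End-to-end analysis: centering -> g-vectors -> VDFs -> metrology -> fit
-> assignment, with a JSON-serialisable report."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import ang_sep_mod180
from .burgers import (burgers_azimuth, classify_character,
                      fit_displacement_model, invisibility_set,
                      screw_handedness)
from .contours import (DislocationLine, auto_seeds, build_profile,
                       detect_uniform_shift, measure_displacement)
from .crystal import UnitCell, ZoneAxis, assign_slip_system, index_assist, \
    match_burgers
from .datamodel import Dataset4D
from .discs import consolidate_gvectors, flag_usable, vdf
from .errors import (EmptyProfileError, FitRefusedError, GeometryError,
                     NoResolvableDistortion, SedlabError, TraceError)

__all__ = ["AnalysisOptions", "analyze_dataset"]

REPORT_SCHEMA = "sedlab-report/1"


@dataclass
class AnalysisOptions:
    """Tunable knobs of the analysis chain (defaults match the library)."""

    aperture_radius: float = 0.02  # 1/A
    sample_fraction: float = 0.05
    cluster_tol: float = 0.012  # 1/A
    seed: int = 0
    skip_centering: bool = False
    affine: np.ndarray | None = None
    n_boot: int = 199
    zero_tol: float = 2.0
    invisibility_angle_tol: float = 10.0
    min_crossing_deg: float = 15.0
    screw_tol: float = 15.0
    edge_tol: float = 15.0
    handedness_align_tol: float = 20.0
    cell: UnitCell | None = None
    zone: ZoneAxis | None = None
    candidate_zones: list = field(default_factory=list)
    burgers_candidates: list | None = None
    match_tol: float = 3.0


def _g_summary(g):
    return {"k": [float(g.k[0]), float(g.k[1])],
            "magnitude": round(g.magnitude, 6),
            "phi": round(float(g.phi), 4),
            "hkl": list(g.hkl) if g.hkl else None,
            "usable": bool(g.usable)}


def analyze_dataset(ds: Dataset4D, line: DislocationLine,
                    opts: AnalysisOptions | None = None) -> dict:
    """Run the full dislocation-characterisation chain on one dataset.

    Every stochastic step is seeded from ``opts.seed``, so the same dataset
    and options give an identical report.  Stage failures degrade gracefully
    into a partial report with a stage-tagged error entry.
    """
    opts = opts or AnalysisOptions()
    report = {"schema": REPORT_SCHEMA, "seed": opts.seed, "errors": [],
              "qc": {}}

    if opts.skip_centering:
        centred = ds
    else:
        from .preprocess import center_and_correct
        centred, _calib = center_and_correct(ds, affine=opts.affine)

    gvs = consolidate_gvectors(centred, opts.sample_fraction,
                               opts.cluster_tol, seed=opts.seed)
    if not gvs:
        report["errors"].append({"stage": "discs", "error": "no g-vectors"})
        return report
    vdfs = flag_usable([vdf(centred, g, opts.aperture_radius) for g in gvs])
    usable_vdfs = [v for v in vdfs if v.g.usable]
    report["n_gvectors"] = len(gvs)
    report["gvectors"] = [_g_summary(g) for g in gvs]

    rows = []
    if len(usable_vdfs) >= 3:
        rows = detect_uniform_shift(usable_vdfs)
    report["qc"]["uniform_shift_rows"] = rows

    crossings = []
    for v in usable_vdfs:
        try:
            seeds = auto_seeds(v, line)
            c = measure_displacement(v, line, seeds,
                                     min_crossing_deg=opts.min_crossing_deg,
                                     excluded_rows=rows)
        except (TraceError, GeometryError, ValueError) as exc:
            from .contours import ContourCrossing
            c = ContourCrossing(g=v.g, usable=False, reason=str(exc))
        crossings.append(c)
    report["crossings"] = [
        {"phi": round(float(c.g.phi), 4),
         "displacement_nm": None if np.isnan(c.displacement)
         else round(float(c.displacement), 4),
         "uncertainty_nm": None if np.isnan(c.uncertainty)
         else round(float(c.uncertainty), 4),
         "usable": bool(c.usable), "reason": c.reason}
        for c in crossings]
    report["qc"]["unusable_g"] = sum(not c.usable for c in crossings)

    try:
        profile = build_profile(crossings)
    except (EmptyProfileError, ValueError) as exc:
        report["errors"].append({"stage": "profile", "error": str(exc)})
        return report

    try:
        fit = fit_displacement_model(profile, n_boot=opts.n_boot,
                                     seed=opts.seed, zero_sigma=opts.zero_tol)
    except FitRefusedError as exc:
        report["errors"].append({"stage": "fit", "error": str(exc)})
        return report
    report["fit"] = {
        "A_nm": round(fit.amp_A, 5), "B": round(fit.shape_B, 5),
        "C_deg": None if fit.phase_C is None else round(fit.phase_C, 4),
        "ci": {k: [round(v[0], 4), round(v[1], 4)]
               for k, v in fit.ci.items()},
        "rms_nm": None if np.isnan(fit.rms) else round(fit.rms, 5),
        "status": fit.status, "ci_method": fit.ci_method,
        "n_points": fit.n_points,
    }
    if not fit.ok:
        report["result"] = "no resolvable distortion"
        return report

    b_az = burgers_azimuth(fit)
    report["burgers_azimuth_deg"] = round(b_az, 4)
    report["burgers_azimuth_ambiguity"] = "180 deg (intrinsic)"

    inv = invisibility_set(profile, fit, zero_tol=opts.zero_tol,
                           angle_tol=opts.invisibility_angle_tol)
    report["invisible_g"] = [_g_summary(g) for g in inv.gvectors]
    if inv.note:
        report["qc"]["unconstrained_invisibility"] = inv.note

    char = classify_character(b_az, line, opts.screw_tol, opts.edge_tol)
    handed = "undetermined"
    pair = _find_pair_near_u(usable_vdfs, line, opts.handedness_align_tol)
    if pair is not None:
        try:
            handed = screw_handedness(pair, line,
                                      align_tol=opts.handedness_align_tol,
                                      excluded_rows=rows)
        except (ValueError, SedlabError):
            handed = "undetermined"
    char.handedness = handed
    report["character"] = {
        "angle_Bu_deg": round(char.angle_Bu, 3), "label": char.label,
        "handedness": char.handedness,
        "edge_component_azimuth_deg":
            None if char.edge_component_azimuth is None
            else round(char.edge_component_azimuth, 3),
    }

    if opts.cell is not None and opts.zone is not None:
        try:
            report["crystal"] = _crystal_stage(gvs, b_az, line, opts)
        except (ValueError, NoResolvableDistortion) as exc:
            report["errors"].append({"stage": "crystal", "error": str(exc)})
    return report


def _find_pair_near_u(vdfs, line, align_tol):
    u_az = line.u_azimuth
    near = [v for v in vdfs
            if float(ang_sep_mod180(v.g.phi, u_az)) <= align_tol]
    for v in near:
        mate = [w for w in near if w is not v
                and np.allclose(w.g.k, -np.asarray(v.g.k), atol=0.01)]
        if mate:
            return (v, mate[0])
    return None


def _crystal_stage(gvs, b_az, line, opts):
    """Index the pattern, match the Burgers azimuth to a lattice direction
    and name the slip system."""
    zones = opts.candidate_zones or [opts.zone]
    idx = index_assist(gvs, opts.cell, zones)
    out = {}
    if idx == "unindexed":
        out["zone"] = "unindexed"
        return out
    zone, score, rot, assigned = idx[0]
    out["zone"] = list(zone.uvw)
    out["index_score"] = round(float(score), 3)
    out["orientation_offset_deg"] = round(float(rot), 3)
    for i, hkl in assigned.items():
        gvs[i].hkl = tuple(hkl)
    b_az_crystal = b_az - rot
    matches, best = match_burgers(b_az_crystal, opts.cell, zone,
                                  candidates=opts.burgers_candidates,
                                  tol=opts.match_tol)
    if matches:
        m = matches[0]
        out["burgers_uvw"] = list(m.uvw)
        out["burgers_mismatch_deg"] = round(m.mismatch_deg, 3)
        slip = assign_slip_system(m.uvw, line, zone, opts.cell,
                                  orientation_offset=rot)
        out["slip_system"] = slip["label"]
        out["slip_plane"] = list(slip["plane"]) if slip["plane"] else None
    else:
        out["burgers_uvw"] = None
        out["unmatched_best"] = {"uvw": list(best.uvw),
                                 "mismatch_deg": round(best.mismatch_deg, 3)}
    return out
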