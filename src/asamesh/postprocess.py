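"""Derived quantities from solved contraction states.

Turns the solver trajectory into the reported observables: a geometric
partition of the template into "junction" disks (the four-pillar
interstices where mesh struts meet) and "contracted" ellipses (the
mid-strut segments between adjacent junctions), area-weighted stress
statistics per region class, and per-pillar contact/detachment reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UnsupportedLatticeError
from .geometry import PillarLayout, TissueDomain, _tri_areas, classify_pillars
from .solver import DeformationState


@dataclass(frozen=True)
class Ellipse:
    center: np.ndarray
    semi_x: float
    semi_y: float
    orientation: str  # "X" or "Y": direction of the long axis / strut

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (np.atleast_2d(pts) - self.center) / np.array([self.semi_x, self.semi_y])
        return (d**2).sum(axis=1) <= 1.0


@dataclass
class RegionPartition:
    """Junction disks and contracted ellipses on the reference template."""

    junction_centers: np.ndarray
    junction_radius: float
    ellipses: list[Ellipse]

    @property
    def n_junctions(self) -> int:
        return len(self.junction_centers)

    @property
    def n_contracted(self) -> int:
        return len(self.ellipses)


def classify_regions(layout: PillarLayout, r_j: float | None = None) -> RegionPartition:
    """Partition a square-lattice template into junction and contracted regions.

    Junction disks (radius ``r_j``, default interval/2) sit at the
    interstitial points equidistant from four neighbouring pillars.
    Contracted ellipses sit midway between adjacent junction centers, long
    axis along the connecting direction, with semi-axes
    (pitch/2 - r_j, r_j/2).  An n_x x n_y grid yields (n_x-1)(n_y-1)
    junctions and (n_x-2)(n_y-1) + (n_x-1)(n_y-2) ellipses.
    """
    if layout.lattice_kind != "square" or layout.pitch is None:
        raise UnsupportedLatticeError("region classification requires a square lattice")
    pitch = layout.pitch
    if r_j is None:
        r_j = (layout.interval if layout.interval is not None else pitch / 6.0) / 2.0
    xs = np.unique(np.round(layout.centers[:, 0], 9))
    ys = np.unique(np.round(layout.centers[:, 1], 9))
    jx = 0.5 * (xs[:-1] + xs[1:])
    jy = 0.5 * (ys[:-1] + ys[1:])
    gx, gy = np.meshgrid(jx, jy, indexing="ij")
    junctions = np.column_stack([gx.ravel(), gy.ravel()])

    semi_long = pitch / 2.0 - r_j
    semi_short = r_j / 2.0
    ellipses: list[Ellipse] = []
    # X-oriented struts: between junction centers adjacent along x
    for a in range(len(jx) - 1):
        for b in range(len(jy)):
            c = np.array([0.5 * (jx[a] + jx[a + 1]), jy[b]])
            ellipses.append(Ellipse(c, semi_long, semi_short, "X"))
    # Y-oriented struts: between junction centers adjacent along y
    for a in range(len(jx)):
        for b in range(len(jy) - 1):
            c = np.array([jx[a], 0.5 * (jy[b] + jy[b + 1])])
            ellipses.append(Ellipse(c, semi_short, semi_long, "Y"))
    return RegionPartition(junction_centers=junctions, junction_radius=r_j,
                           ellipses=ellipses)


def region_membership(domain: TissueDomain, partition: RegionPartition) -> np.ndarray:
    """Region class of each element by reference centroid.

    Returns an array of strings: "junction", "contracted_X", "contracted_Y"
    or "unassigned".
    """
    cent = domain.nodes[domain.triangles].mean(axis=1)
    labels = np.full(len(cent), "unassigned", dtype=object)
    for e in partition.ellipses:
        labels[e.contains(cent)] = f"contracted_{e.orientation}"
    if partition.n_junctions:
        d = np.linalg.norm(cent[:, None, :] - partition.junction_centers[None, :, :],
                           axis=-1).min(axis=1)
        labels[d <= partition.junction_radius] = "junction"
    return labels


def region_stress_summary(state: DeformationState, domain: TissueDomain,
                          partition: RegionPartition) -> pd.DataFrame:
    """Area-weighted mean |sigma11| and |sigma22| per region class.

    For X-oriented contracted regions the strut axis is X, so sigma11 is the
    component to compare against the junction value (and sigma22 for
    Y-oriented struts).
    """
    labels = region_membership(domain, partition)
    p = domain.nodes[domain.triangles]
    areas = _tri_areas(p)
    s11 = np.abs(state.fields["sigma11"])
    s22 = np.abs(state.fields["sigma22"])
    rows = []
    for cls in ["junction", "contracted_X", "contracted_Y", "unassigned"]:
        sel = labels == cls
        if not sel.any():
            rows.append({"region": cls, "n_elements": 0, "area_um2": 0.0,
                         "mean_abs_sigma11": np.nan, "mean_abs_sigma22": np.nan})
            continue
        w = areas[sel]
        rows.append({
            "region": cls,
            "n_elements": int(sel.sum()),
            "area_um2": float(w.sum()),
            "mean_abs_sigma11": float(np.average(s11[sel], weights=w)),
            "mean_abs_sigma22": float(np.average(s22[sel], weights=w)),
        })
    total_w = areas
    rows.append({
        "region": "total", "n_elements": len(areas), "area_um2": float(areas.sum()),
        "mean_abs_sigma11": float(np.average(s11, weights=total_w)),
        "mean_abs_sigma22": float(np.average(s22, weights=total_w)),
    })
    return pd.DataFrame(rows)


@dataclass
class ContactReport:
    """Per-pillar contact bookkeeping at one or more activation levels."""

    table: pd.DataFrame  # columns: pillar, classification, active_nodes, detached
    detachment_eta: dict[int, float] | None = None


def pillar_contact_report(state: DeformationState, layout: PillarLayout,
                          trajectory: list[DeformationState] | None = None) -> ContactReport:
    """Active contact node counts per pillar; a pillar with zero is detached.

    If the full trajectory is supplied, the detachment activation of each
    pillar (smallest scheduled eta at which its contact count reaches zero
    and stays zero) is reported as well.
    """
    boundary, inner = classify_pillars(layout)
    is_boundary = np.zeros(layout.n_pillars, dtype=bool)
    is_boundary[boundary] = True
    rows = []
    for k in range(layout.n_pillars):
        count = len(state.contact_nodes.get(k, ()))
        rows.append({
            "pillar": k,
            "classification": "boundary" if is_boundary[k] else "inner",
            "active_nodes": count,
            "detached": count == 0,
            "min_gap_um": state.min_gap.get(k, np.nan),
        })
    detachment = None
    if trajectory is not None:
        detachment = {}
        for k in range(layout.n_pillars):
            counts = [len(s.contact_nodes.get(k, ())) for s in trajectory]
            eta_det = np.nan
            for s, c in zip(trajectory, counts):
                if c == 0:
                    if np.isnan(eta_det):
                        eta_det = s.eta
                else:
                    eta_det = np.nan
            detachment[k] = float(eta_det)
    return ContactReport(table=pd.DataFrame(rows), detachment_eta=detachment)


def export_fields(state: DeformationState, domain: TissueDomain, path) -> None:
    """Write a solved state as a VTK legacy ASCII unstructured grid."""
    from .vtkio import write_vtk

    write_vtk(path, domain.nodes, domain.triangles,
              point_data={"displacement": state.u},
              cell_data=state.fields,
              comment=(f"asamesh state at eta={state.eta:g}; "
                       "units: um (coords, displacement), mN um^-2 (stress)"))
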