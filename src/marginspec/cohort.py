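"""Site taxonomy, QC/exclusion rules, retention bookkeeping, probe coverage.

The clinical study design behind this package measures diffuse reflectance at
individual *sites* (pixels) on the margins of partial-mastectomy specimens.
Each site carries a pathology diagnosis (normal tissue type or malignancy
with a depth category), a menopausal status inherited from the patient, and
QC flags. Analysis proceeds in three stages with progressively stricter
retention rules; this module implements those rules, the bookkeeping tallies,
and the geometric scheduler that covers a margin's hole grid with probe
placements.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .spectral import OpticalSummary, WavelengthGrid

__all__ = [
    "ExclusionReason",
    "SiteRecord",
    "CohortTally",
    "lymphazurin_dominant",
    "extreme_outliers",
    "apply_retention",
    "tally",
    "placement_coverage",
    "make_reference_cohort",
]

NORMAL_CLASSES = ("A", "Mx", "FA", "V", "FG", "F", "FCC", "FN")
MALIGNANT_CLASSES = ("IDC", "DCIS", "ILC", "LCIS")
DEPTH_CATEGORIES = ("0 mm", "0+-1 mm", "1+-2 mm")
#: classes admitted to the predominant-tissue-type (stage-2) analysis
STAGE2_NORMAL = ("FG", "FA", "A")
STAGE2_MALIGNANT = ("IDC", "DCIS")


class ExclusionReason(enum.Enum):
    NO_DIAGNOSIS = "no_diagnosis"
    EXCESS_LYMPHAZURIN = "excess_lymphazurin"
    MISSING_DIAGNOSIS_FIELD = "missing_diagnosis_field"
    UNKNOWN_DISTANCE = "unknown_distance"
    EXTREME_OUTLIER = "extreme_outlier"
    MINOR_TISSUE_TYPE_STAGE2 = "minor_tissue_type_stage2"
    HETEROGENEOUS_SITE_STAGE2 = "heterogeneous_site_stage2"
    MENOPAUSE_UNKNOWN_STAGE3 = "menopause_unknown_stage3"


@dataclass
class SiteRecord:
    """One measured margin site."""

    site_id: str
    patient_id: str
    margin_id: str
    top_class: str  # normal | malignant | unidentifiable
    tissue_class: str | None = None
    depth_category: str | None = None
    distance_mm: float | None = None
    menopause: str = "unknown"  # pre | post | peri | unknown
    spectrum: np.ndarray | None = None
    qc_flags: frozenset = frozenset()
    heterogeneous_margin: bool = False
    truth: dict | None = None  # ground-truth parameters for synthetic sites
    fit: object | None = None
    optical: OpticalSummary | None = None

    def __post_init__(self) -> None:
        if self.top_class not in ("normal", "malignant", "unidentifiable"):
            raise ValueError(f"unknown top class {self.top_class!r}")
        if self.top_class == "malignant":
            if self.depth_category not in DEPTH_CATEGORIES:
                raise ValueError("malignant sites need a depth category")
            if self.tissue_class not in MALIGNANT_CLASSES:
                raise ValueError("malignant sites need a malignant tissue class")
            if self.distance_mm is not None:
                self._check_distance()
        elif self.top_class == "normal":
            if self.tissue_class not in NORMAL_CLASSES:
                raise ValueError("normal sites need a normal tissue class")

    def _check_distance(self) -> None:
        d, cat = self.distance_mm, self.depth_category
        ok = (
            (cat == "0 mm" and d == 0.0)
            or (cat == "0+-1 mm" and 0.0 < d <= 1.0)
            or (cat == "1+-2 mm" and 1.0 < d <= 2.0)
        )
        if not ok:
            raise ValueError(
                f"distance {d} mm inconsistent with depth category {cat!r}"
            )


@dataclass(frozen=True)
class CohortTally:
    """Counts by class/category plus margin and patient totals."""

    n_sites: int
    by_top_class: dict
    by_tissue_class: dict
    by_depth_category: dict
    by_menopause: dict
    n_margins: int
    n_patients: int

    def __post_init__(self) -> None:
        if sum(self.by_top_class.values()) != self.n_sites:
            raise ValueError("top-class counts do not sum to total")


def lymphazurin_dominant(spectrum: np.ndarray, grid: WavelengthGrid) -> bool:
    """Dye-dominance QC rule: flag iff R(600 nm) < R(450 nm), strictly.

    Heavy Lymphazurin absorbs strongly near 600 nm, inverting the usual
    hemoglobin-dominated spectral slope; ties retain the site.
    """
    lo, hi = grid.span
    if lo > 450.0 + 1e-9 or hi < 600.0 - 1e-9:
        raise ValueError("grid must cover both 450 and 600 nm")
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != grid.wavelengths.shape:
        raise ValueError("spectrum/grid shape mismatch")
    r450 = spectrum[grid.index_of(450.0)]
    r600 = spectrum[grid.index_of(600.0)]
    return bool(r600 < r450)


def extreme_outliers(values, k: float = 3.0) -> np.ndarray:
    """Fence rule: flag values beyond k·IQR outside the quartiles.

    Quartiles use linear interpolation (numpy default, type 7). Strict
    inequality, so a constant vector has no outliers.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values for the IQR fence rule")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


def _stage_reasons(site: SiteRecord, stage: int) -> list[ExclusionReason]:
    reasons: list[ExclusionReason] = []
    if site.top_class == "unidentifiable":
        reasons.append(ExclusionReason.NO_DIAGNOSIS)
    for flag in (
        ExclusionReason.EXCESS_LYMPHAZURIN,
        ExclusionReason.MISSING_DIAGNOSIS_FIELD,
        ExclusionReason.UNKNOWN_DISTANCE,
        ExclusionReason.EXTREME_OUTLIER,
    ):
        if flag in site.qc_flags:
            reasons.append(flag)
    if stage == 2 and not reasons:
        if site.heterogeneous_margin:
            reasons.append(ExclusionReason.HETEROGENEOUS_SITE_STAGE2)
        elif site.top_class == "normal" and site.tissue_class not in STAGE2_NORMAL:
            reasons.append(ExclusionReason.MINOR_TISSUE_TYPE_STAGE2)
        elif (
            site.top_class == "malignant"
            and site.tissue_class not in STAGE2_MALIGNANT
        ):
            reasons.append(ExclusionReason.MINOR_TISSUE_TYPE_STAGE2)
    if stage == 3 and not reasons:
        if site.top_class != "normal":
            reasons.append(ExclusionReason.MINOR_TISSUE_TYPE_STAGE2)
        elif site.menopause not in ("pre", "post"):
            reasons.append(ExclusionReason.MENOPAUSE_UNKNOWN_STAGE3)
    return reasons


def apply_retention(cohort, stage: int):
    """Apply the stage-1/2/3 retention rules.

    Stage 1 removes sites without a microscopic diagnosis and sites flagged
    for excess Lymphazurin, a missing diagnosis field, unknown tumor
    distance, or extreme-outlier optical signal. Stage 2 additionally keeps
    only predominant tissue types (FG/FA/A among normals, IDC/DCIS among
    malignants) and drops the heterogeneous margin. Stage 3 keeps stage-1
    normal sites from patients with known pre/post menopausal status.

    Returns ``(retained, tally, exclusion_log)`` where the log maps site id
    to the triggering reasons. Deterministic and idempotent.
    """
    if stage not in (1, 2, 3):
        raise ValueError(f"unknown retention stage {stage}")
    # note: stage 3 applies to normal sites only, per the study design
    retained: list[SiteRecord] = []
    log: dict[str, list[ExclusionReason]] = {}
    for site in cohort:
        reasons = _stage_reasons(site, stage)
        if reasons:
            log[site.site_id] = reasons
        else:
            retained.append(site)
    return retained, tally(retained), log


def tally(cohort) -> CohortTally:
    """Count sites by class, depth, menopausal status, margin and patient."""
    by_top: dict = {}
    by_tissue: dict = {}
    by_depth: dict = {}
    by_meno: dict = {}
    margins, patients = set(), set()
    n = 0
    for s in cohort:
        n += 1
        by_top[s.top_class] = by_top.get(s.top_class, 0) + 1
        if s.tissue_class:
            by_tissue[s.tissue_class] = by_tissue.get(s.tissue_class, 0) + 1
        if s.depth_category:
            by_depth[s.depth_category] = by_depth.get(s.depth_category, 0) + 1
        by_meno[s.menopause] = by_meno.get(s.menopause, 0) + 1
        margins.add(s.margin_id)
        patients.add(s.patient_id)
    return CohortTally(
        n_sites=n,
        by_top_class=by_top,
        by_tissue_class=by_tissue,
        by_depth_category=by_depth,
        by_menopause=by_meno,
        n_margins=len(margins),
        n_patients=len(patients),
    )


def placement_coverage(extent_mm: tuple[float, float], geometry) -> tuple[int, int]:
    """Schedule probe placements over a margin's 5 mm hole grid.

    The 4×2 channel array at 10 mm pitch samples 8 holes per placement; four
    interleaved placements (2×2 sub-shifts of the 5 mm hole pitch) cover one
    40×20 mm block, every hole exactly once. Returns
    ``(n_placements, n_holes)``; raises if the extent is smaller than one
    channel-array footprint or does not tile.
    """
    pitch = geometry.grid_pitch_mm
    ch_pitch = geometry.channel_pitch_mm
    ncx, ncy = geometry.channel_array
    w, h = extent_mm
    for v in (w, h):
        if abs(v / pitch - round(v / pitch)) > 1e-9:
            raise ValueError("margin extent must be a multiple of the hole pitch")
    nx, ny = int(round(w / pitch)), int(round(h / pitch))
    step = int(round(ch_pitch / pitch))  # hole indices per channel pitch (2)
    bx, by = ncx * step, ncy * step  # block size in holes (8 × 4)
    if nx < bx or ny < by:
        # allow the probe rotated 90 degrees for tall margins
        if nx >= by and ny >= bx:
            nx, ny, bx, by = ny, nx, bx, by
        else:
            raise ValueError("margin extent smaller than one probe footprint")
    if nx % bx or ny % by:
        raise ValueError("margin extent does not tile with the channel array")
    covered = np.zeros((nx, ny), dtype=int)
    n_placements = 0
    for ax0 in range(0, nx, bx):
        for ay0 in range(0, ny, by):
            for px in range(step):
                for py in range(step):
                    n_placements += 1
                    for i in range(ncx):
                        for j in range(ncy):
                            covered[ax0 + px + step * i, ay0 + py + step * j] += 1
    if not np.all(covered == 1):
        raise AssertionError("placement schedule failed to cover each hole once")
    return n_placements, nx * ny


# ---------------------------------------------------------------------------
# packaged bookkeeping cohort (regression fixture, synthesized ids)
# ---------------------------------------------------------------------------

#: Site-classification table of the retained cohort: class -> count
TABLE1_NORMAL = {
    "A": 324, "Mx": 112, "FA": 60, "V": 64, "FG": 24, "F": 6, "FCC": 4, "FN": 1,
}
TABLE1_MALIGNANT = {
    ("0 mm", "IDC"): 8, ("0 mm", "DCIS"): 2,
    ("0+-1 mm", "IDC"): 9, ("0+-1 mm", "DCIS"): 5,
    ("0+-1 mm", "ILC"): 1, ("0+-1 mm", "LCIS"): 2,
    ("1+-2 mm", "IDC"): 5, ("1+-2 mm", "DCIS"): 5, ("1+-2 mm", "LCIS"): 1,
}

_DEPTH_MID = {"0 mm": 0.0, "0+-1 mm": 0.5, "1+-2 mm": 1.5}


def make_reference_cohort() -> list[SiteRecord]:
    """The study's site-flow bookkeeping as a synthetic regression fixture.

    854 sites from 105 margins (104 patients): 91 without a microscopic
    diagnosis; 763 diagnosed (715 normal / 48 malignant); 120 normal and 10
    malignant sites carry stage-1 QC flags, leaving 595 normal + 38 malignant
    sites on 101 margins (100 patients). One margin with heterogeneous sites
    (2 IDC + mixed-type normals) drops at stage 2; 6 patients (7 margins,
    one patient with two margins) lack pre/post menopausal status and drop
    from the stage-3 normal-site analysis, leaving 553 normal sites. Ids are
    synthesized; this is a bookkeeping fixture, not patient data.
    """
    sites: list[SiteRecord] = []
    sid = iter(range(1, 10_000))

    # margins m001..m105; patient p001 contributes m001 and m002
    def margin_patient(i: int) -> tuple[str, str]:
        if i <= 2:
            return f"m{i:03d}", "p001"
        return f"m{i:03d}", f"p{i - 1:03d}"

    # menopause by patient: p001 (two margins) + p002..p006 unknown/peri;
    # these carry the 42 stage-3-excluded normal sites over 7 margins
    def patient_status(pid: str) -> str:
        if pid == "p001":
            return "peri"
        if pid in {"p002", "p003", "p004", "p005", "p006"}:
            return "unknown"
        return "post"  # provisional; a pre-menopausal block is set below

    def add(n, top, tissue=None, depth=None, margin_i=None, flags=(), hetero=False):
        for _ in range(n):
            mid, pid = margin_patient(margin_i)
            sites.append(
                SiteRecord(
                    site_id=f"s{next(sid):04d}",
                    patient_id=pid,
                    margin_id=mid,
                    top_class=top,
                    tissue_class=tissue,
                    depth_category=depth,
                    distance_mm=_DEPTH_MID[depth] if depth else None,
                    menopause=patient_status(pid) if top != "unidentifiable" else "unknown",
                    qc_flags=frozenset(flags),
                    heterogeneous_margin=hetero,
                )
            )

    # --- retained normal sites, spread so every analysis margin m001..m101
    # keeps a predominant-type site (m050 is the heterogeneous margin)
    hetero_margin = 50
    analysis_margins = [i for i in range(1, 102) if i != hetero_margin]
    pool = []
    for cls, cnt in TABLE1_NORMAL.items():
        pool.extend([cls] * cnt)
    # guarantee one A site per analysis margin, then round-robin the rest
    per_margin: dict[int, list[str]] = {i: [] for i in range(1, 102)}
    a_left = TABLE1_NORMAL["A"]
    for i in analysis_margins:
        per_margin[i].append("A")
        a_left -= 1
    rest = (["A"] * a_left) + [c for c in pool if c != "A"]
    # the heterogeneous margin receives only mixed-type normals
    per_margin[hetero_margin] = ["Mx", "Mx", "V"]
    rest_iter = [c for c in rest]
    for cls in ("Mx", "Mx", "V"):
        rest_iter.remove(cls)
    k = 0
    for cls in rest_iter:
        per_margin[analysis_margins[k % len(analysis_margins)]].append(cls)
        k += 1
    for i in range(1, 102):
        for cls in per_margin[i]:
            add(1, "normal", tissue=cls, margin_i=i)

    # --- retained malignant sites on analysis margins; the 2 stage-2-excluded
    # IDC sites live on the heterogeneous margin
    malig = []
    for (depth, cls), cnt in TABLE1_MALIGNANT.items():
        malig.extend([(depth, cls)] * cnt)
    hetero_malig = [("0+-1 mm", "IDC"), ("0+-1 mm", "IDC")]
    for d, cls in hetero_malig:
        malig.remove((d, cls))
        add(1, "malignant", tissue=cls, depth=d, margin_i=hetero_margin, hetero=True)
    for j, (d, cls) in enumerate(malig):
        add(1, "malignant", tissue=cls, depth=d, margin_i=analysis_margins[j % 60])

    # --- stage-1 exclusions: 120 normal + 10 malignant flagged sites,
    # parked on margins m102..m105 so those margins vanish at stage 1
    F = ExclusionReason
    flagged_normal = (
        [(F.EXCESS_LYMPHAZURIN,)] * 60
        + [(F.MISSING_DIAGNOSIS_FIELD,)] * 30
        + [(F.EXTREME_OUTLIER,)] * 30
    )
    for j, fl in enumerate(flagged_normal):
        add(1, "normal", tissue="A", margin_i=102 + j % 4, flags=fl)
    flagged_malig = (
        [(F.EXCESS_LYMPHAZURIN,)] * 4
        + [(F.MISSING_DIAGNOSIS_FIELD,)] * 2
        + [(F.UNKNOWN_DISTANCE,)] * 2
        + [(F.EXTREME_OUTLIER,)] * 2
    )
    for j, fl in enumerate(flagged_malig):
        add(1, "malignant", tissue="IDC", depth="0 mm", margin_i=102 + j % 4, flags=fl)

    # --- 91 sites without a diagnosis
    add(91, "unidentifiable", margin_i=103)

    # --- menopausal block structure: the unknown/peri patients (margins
    # m001..m007) must hold exactly 42 retained normal sites, the stage-3
    # exclusions. Rebalance round-robin extras between m007 and m008 —
    # moving a non-guaranteed extra keeps every margin non-empty and keeps
    # the per-class totals intact.
    def move_to(s: SiteRecord, margin_i: int) -> None:
        mid, pid = margin_patient(margin_i)
        s.margin_id, s.patient_id = mid, pid
        s.menopause = patient_status(pid)

    def extras_on(margin_i: int) -> list[SiteRecord]:
        mid = f"m{margin_i:03d}"
        block = [
            s for s in sites
            if s.margin_id == mid and s.top_class == "normal" and not s.qc_flags
        ]
        keep_a = next((s for s in block if s.tissue_class == "A"), None)
        return [s for s in block if s is not keep_a]

    unk_margins = {f"m{i:03d}" for i in range(1, 8)}
    def unknown_block():
        return [
            s for s in sites
            if s.margin_id in unk_margins
            and s.top_class == "normal" and not s.qc_flags
        ]

    donor = 8
    while len(unknown_block()) < 42:
        pool42 = extras_on(donor)
        if not pool42:
            donor += 1
            continue
        move_to(pool42[0], 7)
    surplus = len(unknown_block()) - 42
    while surplus > 0:
        for i in range(7, 0, -1):
            pool42 = extras_on(i)
            if pool42:
                move_to(pool42[0], 8)
                surplus -= 1
                break
        else:
            raise AssertionError("cannot rebalance unknown-status block")

    # --- of the remaining normal sites, 142 are pre-menopausal and 411
    # post-menopausal; assign whole margins where possible
    known = [
        s for s in sites
        if s.top_class == "normal" and not s.qc_flags
        and s.margin_id not in unk_margins
    ]
    by_margin: dict[str, list[SiteRecord]] = {}
    for s in known:
        by_margin.setdefault(s.margin_id, []).append(s)
    pre_left = 142
    for mid in sorted(by_margin):
        block = by_margin[mid]
        take = block if len(block) <= pre_left else block[:pre_left]
        for s in take:
            s.menopause = "pre"
        pre_left -= len(take)
        if pre_left == 0:
            break
    return sites
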