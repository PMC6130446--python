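"""Family-structured synthetic rs-fMRI cohorts with known ground truth.

Subject-level conditional-dependence structure is planted in the precision
(inverse covariance) domain: each subject's precision matrix shares a
sparse base edge pattern, and per-subject edge weights decompose into an
additive genetic field (correlated across subjects according to kinship:
MZ = 1, DZ/sibling = 0.5, unrelated = 0), a family-shared environment
field, and a unique field, with tunable variance fractions g2/c2/e2.
Planting in the precision domain makes the true connectotype analytically
available: b_ij = -theta_ij / theta_ii.

Time courses are zero-mean multivariate Gaussian draws from the subject
covariance (the precision inverse), optionally AR(1)-smoothed in time so
prewhitening is exercised.  The generator does not emulate hemodynamics,
scanner noise spectra, or realistic motion spike trains.

Scaled-down defaults (M = 30 ROIs, 240 frames — the average frame count
surviving motion censoring in a typical 3 x 5-minute pediatric protocol)
keep desk-scale experiments fast; family templates default to the
HCP-style mix of 10 MZ, 11 DZ and 58 nontwin-sibling pairs plus 70
singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from connectokin.cohort_io import (
    Cohort,
    KNOWN_NETWORKS,
    ParcellationTable,
    ScanTimeSeries,
)
from connectokin.heritability import PairOutcomes

logger = logging.getLogger(__name__)

KINSHIP = {"MZ": 1.0, "DZ": 0.5, "sibling": 0.5, "unrelated": 0.0}

#: HCP-style family mix: (template, count); templates are "MZ", "DZ",
#: "sib" (nontwin sibling pair), "sib3" (nontwin sibling trio, three
#: pairwise sibling pairs) and "singleton".  The mix reproduces the adult
#: sample's structure: 70 one-, 49 two- and 10 three-descendant families =
#: 198 subjects carrying 10 MZ + 11 DZ + 58 nontwin sibling pairs.
HCP_TEMPLATES = (("MZ", 10), ("DZ", 11), ("sib", 28), ("sib3", 10),
                 ("singleton", 70))


@dataclass
class SyntheticSpec:
    """Declarative description of a synthetic cohort."""

    family_templates: tuple = HCP_TEMPLATES
    M: int = 30
    frames: int = 240
    scans_per_subject: int = 1
    tr: float = 2.5
    g2: float = 0.4
    c2: float = 0.2
    e2: float = 0.4
    base_density: float = 0.15
    base_weight_sd: float = 0.1
    subject_weight_sd: float = 0.3
    ar_phi: float = 0.3
    seed: int = 0
    #: seed for the shared structural draw (edge support, base weights,
    #: familial-edge placement).  Two cohorts generated with the same
    #: structure_seed share a "brain" — ROI j means the same thing in both —
    #: which is what makes cross-dataset transfer possible.  None: use seed.
    structure_seed: int | None = None
    #: 0-based ROI indices whose incident edges carry the familial
    #: (genetic + shared-environment) structure; None plants it everywhere.
    familial_rois: tuple | None = None

    def __post_init__(self):
        fr = (self.g2, self.c2, self.e2)
        if any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1) > 1e-9:
            raise ValueError(f"variance fractions must be in [0,1] and sum to 1, got {fr}")
        if self.M < 5:
            raise ValueError("M must be >= 5")
        if self.frames < 30:
            raise ValueError("frames must be >= 30")

    @property
    def n_families(self) -> int:
        return sum(n for _, n in self.family_templates)


@dataclass
class SyntheticTruth:
    """Ground truth: per-subject precision and coefficient matrices."""

    precisions: dict  # subject_id -> (M, M) SPD ndarray
    B_true: dict  # subject_id -> (M, M) zero-diagonal ndarray
    kinship: pd.DataFrame  # subject_a, subject_b, kinship (pairs with > 0)
    edge_index: np.ndarray  # (n_edges, 2) upper-triangular support
    familial_edges: np.ndarray = None  # bool mask over edge_index rows
    spec: SyntheticSpec = None


def make_pedigree(spec: SyntheticSpec) -> Cohort:
    """Instantiate families from templates, with scan sessions as ordinals."""
    if spec.n_families == 0:
        raise ValueError("zero families")
    subjects, scans, zyg = [], [], []
    fam_no = 0
    for kind, count in spec.family_templates:
        for _ in range(count):
            fam_no += 1
            fid = f"F{fam_no:04d}"
            if kind == "singleton":
                members = [f"{fid}_S1"]
            elif kind in ("MZ", "DZ", "sib"):
                members = [f"{fid}_S1", f"{fid}_S2"]
                zyg.append((members[0], members[1],
                            {"MZ": "MZ", "DZ": "DZ", "sib": "sibling"}[kind]))
            elif kind == "sib3":
                members = [f"{fid}_S1", f"{fid}_S2", f"{fid}_S3"]
                for x in range(3):
                    for y in range(x + 1, 3):
                        zyg.append((members[x], members[y], "sibling"))
            else:
                raise ValueError(f"unknown family template {kind!r}")
            for s in members:
                subjects.append((s, fid))
                for sess in range(1, spec.scans_per_subject + 1):
                    scans.append((f"{s}_scan{sess}", s, str(sess)))
    return Cohort(
        subjects=pd.DataFrame(subjects, columns=["subject_id", "family_id"]),
        scans=pd.DataFrame(scans, columns=["scan_id", "subject_id", "session"]),
        zygosity_pairs=pd.DataFrame(zyg, columns=["subject_a", "subject_b",
                                                  "zygosity"]),
    )


def make_oregon_like_pedigree() -> Cohort:
    """A roster with the longitudinal youth sample's printed bookkeeping:
    159 subjects (131 with one scan, 27 with two, 1 with three; 188 scans)
    and 16 sibling pairs whose scan counts yield 46 ordered sibling
    scan-pair comparisons (11 pairs with 1+1 scans, 4 with 1+2, 1 with 2+2:
    2 * (11*1 + 4*2 + 1*4) = 46)."""
    subjects, scans = [], []
    zyg = []

    def add_subject(sid, fid, n_scans):
        subjects.append((sid, fid))
        for k in range(1, n_scans + 1):
            scans.append((f"{sid}_scan{k}", sid, str(k)))

    fam = 0
    sib_scan_counts = [(1, 1)] * 11 + [(1, 2)] * 4 + [(2, 2)]
    for na, nb in sib_scan_counts:
        fam += 1
        add_subject(f"F{fam:04d}_S1", f"F{fam:04d}", na)
        add_subject(f"F{fam:04d}_S2", f"F{fam:04d}", nb)
        zyg.append((f"F{fam:04d}_S1", f"F{fam:04d}_S2", "sibling"))
    # sibling subjects so far: 32, carrying 6 two-scan subjects
    # remaining singletons: 105 one-scan + 21 two-scan + 1 three-scan = 127
    for n_scans, count in ((1, 105), (2, 21), (3, 1)):
        for _ in range(count):
            fam += 1
            add_subject(f"F{fam:04d}_S1", f"F{fam:04d}", n_scans)
    return Cohort(
        subjects=pd.DataFrame(subjects, columns=["subject_id", "family_id"]),
        scans=pd.DataFrame(scans, columns=["scan_id", "subject_id", "session"]),
        zygosity_pairs=pd.DataFrame(zyg, columns=["subject_a", "subject_b",
                                                  "zygosity"]),
    )


def make_parcellation(n_cortical: int = 333, n_unassigned: int = 47,
                      n_subcortical: int = 19, seed: int = 0) -> ParcellationTable:
    """A Gordon-style parcellation table: cortical ROIs spread over the 12
    cortical networks (with ``n_unassigned`` left unassigned) plus a
    subcortical network."""
    rng = np.random.default_rng(seed)
    cortical_networks = [n for n in KNOWN_NETWORKS
                         if n not in ("subcortical", "unassigned")]
    n_assigned = n_cortical - n_unassigned
    labels = [cortical_networks[i % len(cortical_networks)] for i in range(n_assigned)]
    labels += ["unassigned"] * n_unassigned
    labels += ["subcortical"] * n_subcortical
    n_total = n_cortical + n_subcortical
    table = pd.DataFrame({
        "roi_id": np.arange(1, n_total + 1),
        "network": labels,
        "n_vertices": rng.integers(30, 600, size=n_total),
        "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(n_total)],
    })
    return ParcellationTable(table=table)


def _edge_fields(cohort: Cohort, n_edges: int, rng) -> dict:
    """Per-subject standard-normal genetic edge fields with the kinship
    correlation structure (MZ = 1, DZ/sib = 0.5, unrelated = 0)."""
    zyg = {frozenset((r["subject_a"], r["subject_b"])): r["zygosity"]
           for _, r in cohort.zygosity_pairs.iterrows()}
    fields = {}
    by_family = cohort.subjects.groupby("family_id")["subject_id"].apply(list)
    for fid, members in by_family.items():
        A = rng.standard_normal(n_edges)  # additive familial component
        mz_shared = {}
        for s in members:
            mz_partner = None
            for t in members:
                if t != s and zyg.get(frozenset((s, t))) == "MZ":
                    mz_partner = t
            if mz_partner is not None:
                key = frozenset((s, mz_partner))
                if key not in mz_shared:
                    mz_shared[key] = rng.standard_normal(n_edges)
                unique = mz_shared[key]
            else:
                unique = rng.standard_normal(n_edges)
            fields[s] = np.sqrt(0.5) * A + np.sqrt(0.5) * unique
    return fields


def make_precisions(spec: SyntheticSpec, cohort: Cohort,
                    rng=None, min_eig: float = 0.1,
                    max_loading: float = 5.0) -> SyntheticTruth:
    """Draw the shared sparse edge support and per-subject precision
    matrices with kinship-structured edge weights; derive true connectotype
    coefficients b_ij = -theta_ij/theta_ii."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    M = spec.M
    iu = np.triu_indices(M, k=1)
    density = spec.base_density
    struct = spec.structure_seed if spec.structure_seed is not None else spec.seed
    for attempt in range(4):
        structure_rng = np.random.default_rng([struct, 17, attempt])
        n_possible = len(iu[0])
        on = structure_rng.random(n_possible) < density
        edges = np.column_stack([iu[0][on], iu[1][on]])
        n_edges = len(edges)
        base = structure_rng.standard_normal(n_edges) * spec.base_weight_sd
        if spec.familial_rois is None:
            familial = np.ones(n_edges, dtype=bool)
        else:
            fr = np.asarray(spec.familial_rois)
            familial = np.isin(edges[:, 0], fr) | np.isin(edges[:, 1], fr)
        genetic = _edge_fields(cohort, n_edges, rng)
        family_env = {fid: rng.standard_normal(n_edges)
                      for fid in cohort.subjects["family_id"].unique()}
        fam_of = dict(zip(cohort.subjects["subject_id"],
                          cohort.subjects["family_id"]))
        precisions, B_true = {}, {}
        ok = True
        for s in cohort.subjects["subject_id"]:
            unique = rng.standard_normal(n_edges)
            dev = np.where(
                familial,
                (np.sqrt(spec.g2) * genetic[s]
                 + np.sqrt(spec.c2) * family_env[fam_of[s]]
                 + np.sqrt(spec.e2) * unique),
                unique)
            w = base + spec.subject_weight_sd * dev
            Theta = np.eye(M)
            Theta[edges[:, 0], edges[:, 1]] = w
            Theta[edges[:, 1], edges[:, 0]] = w
            lam = np.linalg.eigvalsh(Theta)[0]
            loading = max(0.0, min_eig - lam)
            if loading > max_loading:
                ok = False
                break
            Theta += loading * np.eye(M)
            precisions[s] = Theta
            B = -Theta / np.diag(Theta)[:, None]
            np.fill_diagonal(B, 0.0)
            B_true[s] = B
        if ok:
            break
        density *= 0.5
        logger.warning("diagonal loading exceeded %.1f; retrying with edge "
                       "density %.3f", max_loading, density)
    else:
        raise RuntimeError("could not build SPD precisions")

    zyg = {frozenset((r["subject_a"], r["subject_b"])): r["zygosity"]
           for _, r in cohort.zygosity_pairs.iterrows()}
    kin_rows = [(min(a, b), max(a, b), KINSHIP[z])
                for (pair, z) in ((tuple(k), v) for k, v in zyg.items())
                for a, b in [pair]]
    kinship = pd.DataFrame(kin_rows, columns=["subject_a", "subject_b", "kinship"])
    return SyntheticTruth(precisions=precisions, B_true=B_true, kinship=kinship,
                          edge_index=edges, familial_edges=familial, spec=spec)


def sample_timeseries(truth: SyntheticTruth, subject_id, scan_id: str,
                      rng, frames: int | None = None) -> ScanTimeSeries:
    """Draw one scan: MVN frames with covariance inv(Theta), optionally
    AR(1)-filtered in time (marginal covariance preserved)."""
    spec = truth.spec
    if frames is None:
        frames = spec.frames
    Theta = truth.precisions[subject_id]
    cov = np.linalg.inv(Theta)
    L = np.linalg.cholesky(cov)
    eps = rng.standard_normal((frames, spec.M)) @ L.T
    phi = spec.ar_phi
    if phi != 0.0:
        eps = signal.lfilter([np.sqrt(1 - phi ** 2)], [1.0, -phi], eps, axis=0)
    return ScanTimeSeries(data=eps, tr=spec.tr, scan_id=scan_id)


def make_fd(n_frames: int, rng, median: float = 0.1, sigma: float = 0.5,
            shift: float = 0.0) -> np.ndarray:
    """Lognormal per-frame displacement trace (mm) with optional additive
    median shift (for planting familial motion as a control)."""
    if shift < 0:
        raise ValueError("shift must be >= 0")
    return np.exp(rng.normal(np.log(median), sigma, size=n_frames)) + shift


def make_anatomy(cohort: Cohort, M: int, rng, g2: float = 0.4, c2: float = 0.2,
                 head_beta: float = 0.5) -> pd.DataFrame:
    """Per-subject per-ROI anatomical measures (thickness, sulcal depth)
    with their own additive genetic / shared / unique structure plus a
    head-size confounder."""
    e2 = 1 - g2 - c2
    genetic = _edge_fields(cohort, 2 * M, rng)
    fam_of = dict(zip(cohort.subjects["subject_id"], cohort.subjects["family_id"]))
    family_env = {fid: rng.standard_normal(2 * M)
                  for fid in cohort.subjects["family_id"].unique()}
    base_thick = rng.normal(2.5, 0.2, size=M)
    base_sulc = rng.normal(1.5, 0.4, size=M)
    rows = []
    for s in cohort.subjects["subject_id"]:
        head = float(rng.normal(1.0, 0.1))
        dev = (np.sqrt(g2) * genetic[s]
               + np.sqrt(c2) * family_env[fam_of[s]]
               + np.sqrt(e2) * rng.standard_normal(2 * M))
        thick = base_thick + 0.15 * dev[:M] + head_beta * (head - 1.0)
        sulc = base_sulc + 0.25 * dev[M:] + head_beta * (head - 1.0)
        for r in range(M):
            rows.append((s, r + 1, thick[r], sulc[r], head))
    return pd.DataFrame(rows, columns=["subject_id", "roi_id", "thickness",
                                       "sulcal_depth", "head_size"])


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: SyntheticTruth
    timeseries: dict  # scan_id -> ScanTimeSeries
    fd: dict  # scan_id -> ndarray
    parcellation: ParcellationTable


def simulate_cohort(spec: SyntheticSpec, with_anatomy: bool = False,
                    fd_family_shift: float = 0.0) -> SimulatedCohort:
    """End-to-end generation: pedigree, precisions, scans, FD traces.

    Deterministic given ``spec`` (including ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed)
    cohort = make_pedigree(spec)
    truth = make_precisions(spec, cohort, rng)
    shifted_fams = set()
    if fd_family_shift > 0:
        fams = cohort.subjects["family_id"].unique()
        shifted_fams = set(fams[: len(fams) // 2])
    fam_of = dict(zip(cohort.subjects["subject_id"], cohort.subjects["family_id"]))
    timeseries, fd = {}, {}
    for _, row in cohort.scans.iterrows():
        sid, subject = row["scan_id"], row["subject_id"]
        timeseries[sid] = sample_timeseries(truth, subject, sid, rng)
        shift = fd_family_shift if fam_of[subject] in shifted_fams else 0.0
        fd[sid] = make_fd(spec.frames, rng, shift=shift)
    if with_anatomy:
        cohort.anatomy = make_anatomy(cohort, spec.M, rng)
    networks = [n for n in KNOWN_NETWORKS if n not in ("subcortical", "unassigned")]
    n_unassigned = max(0, spec.M - 4 * len(networks))
    parcellation = make_parcellation(
        n_cortical=spec.M, n_unassigned=min(n_unassigned, spec.M // 6),
        n_subcortical=0, seed=spec.seed)
    return SimulatedCohort(cohort=cohort, truth=truth, timeseries=timeseries,
                           fd=fd, parcellation=parcellation)


def expected_pair_similarity_ordering(truth: SyntheticTruth) -> dict:
    """Mean cosine similarity of true coefficient matrices by kinship class —
    the planted ordering MZ > DZ/sib > unrelated, computed exactly from the
    generated truth."""
    subs = list(truth.B_true)
    kin = {frozenset((a, b)): k for a, b, k in
           truth.kinship.itertuples(index=False)}
    sims = {"MZ": [], "DZ_or_sib": [], "unrelated": []}
    for i, a in enumerate(subs):
        for b in subs[i + 1:]:
            va = truth.B_true[a].ravel()
            vb = truth.B_true[b].ravel()
            cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
            k = kin.get(frozenset((a, b)), 0.0)
            if k == 1.0:
                sims["MZ"].append(cos)
            elif k == 0.5:
                sims["DZ_or_sib"].append(cos)
            else:
                sims["unrelated"].append(cos)
    return {k: (float(np.mean(v)) if v else None) for k, v in sims.items()}


def make_pair_outcomes(h2: float = 0.2, c2: float = 0.1, n_per_group: int = 58,
                       n_roi: int = 30, n_unrelated_pool: int | None = None,
                       seed=None) -> PairOutcomes:
    """Pair-level outcome matrix with planted ANOVA sum-of-squares fractions.

    Outcomes follow y_{pair,roi} = mu_g + b_roi + noise with group means
    chosen in closed form so that, in a balanced analysis subset
    (``n_per_group`` pairs per genetics level), the expected sequential SS
    fractions are ``c2`` for environment (relatedness) and ``h2`` for
    genetics (MZ vs DZ/sib beyond relatedness).  With c2 = 0 the related
    group mean equals the unrelated mean by construction.  The unrelated
    pool is larger than the matched size so repeated-ANOVA resampling is
    exercised.
    """
    if h2 < 0 or c2 < 0 or h2 + c2 >= 1:
        raise ValueError("need h2, c2 >= 0 and h2 + c2 < 1")
    rng = np.random.default_rng(seed)
    if n_unrelated_pool is None:
        n_unrelated_pool = 4 * n_per_group
    # per-ROI expected SS (per n pairs, unit noise): genetics n*m^2/2,
    # environment (2n/3)*X^2 with X = d + m/2, noise ~ 3n
    T = 3.0 / (1.0 - h2 - c2)
    m = np.sqrt(2.0 * h2 * T)
    X = np.sqrt(1.5 * c2 * T)
    d = X - m / 2.0
    mu = {"MZ": d + m, "DZ_or_sib": d, "unrelated": 0.0}
    genetics = np.array(["MZ"] * n_per_group + ["DZ_or_sib"] * n_per_group
                        + ["unrelated"] * n_unrelated_pool, dtype=object)
    b_roi = rng.normal(0.0, 0.3, size=n_roi)
    mu_vec = np.array([mu[g] for g in genetics])
    Y = (mu_vec[:, None] + b_roi[None, :]
         + rng.standard_normal((len(genetics), n_roi)))
    return PairOutcomes(Y=Y, genetics=genetics)
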