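"""Synthetic inputs for every pipeline stage.

The generators emulate the study conditions end to end: equilibrium
hard-core patterns stand in for contact-inhibited tumours, Thomas cluster
patterns for invasive ones, disk-rendered images for stained-nuclei
regions, exponential survival linked to phenotype for the cohort, and
negative-binomial counts with planted effects for the RNA-seq stage.

The hard-core generator is a spatial birth-and-death chain: in each event
either a division is proposed at a uniform location (rate m per unit area)
or a uniform existing cell dies (rate d per cell); a division succeeds
only if the new cell lies at least h from its nearest neighbour.  With
h = 0 the chain's equilibrium is Poisson with intensity beta = m / d;
with h > 0 it converges to the Gibbs hard-core process with that
intensity and hard-core distance (Preston's equilibrium result, which
the tests verify empirically).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import PointPattern, Window

__all__ = [
    "BirthDeathParams",
    "CohortSpec",
    "CountsSpec",
    "DEFAULT_WINDOW",
    "gen_poisson_pattern",
    "gen_hardcore_pattern",
    "gen_cluster_pattern",
    "gen_histology_image",
    "gen_cohort",
    "gen_counts",
]

#: Default observation region: a 300 um x 300 um square, the size of the
#: randomly chosen histology crops the pipeline is designed around.
DEFAULT_WINDOW = Window(0.0, 300.0, 0.0, 300.0)


# --------------------------------------------------------------------------
# parameter records
# --------------------------------------------------------------------------

@dataclass
class BirthDeathParams:
    """Rates of the spatial birth-and-death chain.

    birth_rate : divisions per unit area per unit time (m)
    death_rate : deaths per cell per unit time (d)
    hard_core  : minimum allowed inter-cell distance h in um
    n_steps    : number of accepted events to run (0 -> use the default
                 burn-in of 10x the expected equilibrium count)
    """

    birth_rate: float
    death_rate: float
    hard_core: float = 0.0
    n_steps: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.death_rate <= 0:
            raise ValueError("birth and death rates must be positive")
        if self.hard_core < 0:
            raise ValueError("hard-core distance must be non-negative")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    @property
    def equilibrium_intensity(self) -> float:
        """beta = m / d, the Gibbs-process intensity."""
        return self.birth_rate / self.death_rate


@dataclass
class CohortSpec:
    """Two-phenotype synthetic cohort: inhibited ('Gibbs') vs clustered
    ('Invasion') patients with phenotype-linked exponential survival."""

    n_gibbs: int = 40
    n_invasion: int = 20
    survival_scale_gibbs: float = 600.0   # days
    survival_scale_invasion: float = 150.0
    censor_fraction: float = 0.1
    # pattern parameters per phenotype
    gibbs_intensity: float = 200.0 / (300.0 * 300.0)  # cells / um^2
    gibbs_hard_core: float = 12.0                     # um
    # patients differ in cell size and packing: per-patient hard core and
    # intensity are jittered by +/- this relative spread
    gibbs_heterogeneity: float = 0.15
    invasion_parent_intensity: float = 25.0 / (300.0 * 300.0)
    invasion_offspring_mean: float = 8.0
    invasion_offspring_sd: float = 6.0
    # invasive tumours are heterogeneous: per-patient Thomas parameters
    # are jittered by +/- this relative spread around the centres above
    invasion_heterogeneity: float = 0.4
    window: Window = field(default_factory=lambda: DEFAULT_WINDOW)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_gibbs < 0 or self.n_invasion < 0:
            raise ValueError("patient counts must be non-negative")
        if self.survival_scale_gibbs <= 0 or self.survival_scale_invasion <= 0:
            raise ValueError("survival scales must be positive")
        if not (0 <= self.censor_fraction < 1):
            raise ValueError("censor_fraction must lie in [0, 1)")


@dataclass
class CountsSpec:
    """Negative-binomial gene x sample counts with a planted DE fraction."""

    n_genes: int = 2000
    n_samples_a: int = 20
    n_samples_b: int = 20
    de_fraction: float = 0.01
    log2_effect: float = 8.0
    dispersion: float = 0.1
    baseline_mean: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.de_fraction <= 1):
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be positive")


# --------------------------------------------------------------------------
# point-pattern generators
# --------------------------------------------------------------------------

def gen_poisson_pattern(intensity: float, window: Window = DEFAULT_WINDOW,
                        seed=None) -> PointPattern:
    """Homogeneous Poisson (CSR) pattern with the given intensity (pts/um^2)."""
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * window.area)
    xy = np.column_stack([
        rng.uniform(window.x_min, window.x_max, n),
        rng.uniform(window.y_min, window.y_max, n),
    ])
    return PointPattern(xy, window)


def gen_hardcore_pattern(params: BirthDeathParams,
                         window: Window = DEFAULT_WINDOW,
                         return_trajectory: bool = False):
    """Equilibrium sample of the hard-core spatial birth-and-death chain.

    Runs the embedded jump chain for ``params.n_steps`` accepted events
    (default: 10x the expected equilibrium count beta * |W|, floor 1000)
    and returns the final state.  Every retained pair of points is at
    least ``hard_core`` apart, by construction.  With
    ``return_trajectory`` the per-event point counts are returned as a
    second value (for stationarity diagnostics).
    """
    rng = np.random.default_rng(params.seed)
    h = params.hard_core
    diag = float(np.hypot(window.width, window.height))
    if h >= diag:
        warnings.warn(
            "hard-core distance exceeds the window diagonal; at most one "
            "point can ever be present", stacklevel=2)

    beta = params.equilibrium_intensity
    expected = beta * window.area
    n_events = params.n_steps or max(1000, int(10 * expected))

    total_birth = params.birth_rate * window.area
    h2 = h * h
    # grow-able coordinate buffer; n stays modest so O(n) distance checks
    # per proposal are cheap
    cap = max(64, int(4 * expected))
    pts = np.empty((cap, 2))
    n = 0
    accepted = 0
    # cap on proposals so a pathological hard core cannot loop forever
    max_proposals = 50 * n_events
    proposals = 0
    trajectory = np.empty(n_events, dtype=int) if return_trajectory else None
    while accepted < n_events and proposals < max_proposals:
        proposals += 1
        total_death = params.death_rate * n
        if rng.random() < total_birth / (total_birth + total_death):
            u = np.array([
                rng.uniform(window.x_min, window.x_max),
                rng.uniform(window.y_min, window.y_max),
            ])
            if n and h > 0:
                d2 = np.sum((pts[:n] - u) ** 2, axis=1)
                if d2.min() < h2:
                    continue  # division forbidden by the hard core
            if n == cap:
                cap *= 2
                pts = np.vstack([pts, np.empty((cap - n, 2))])
            pts[n] = u
            n += 1
        else:
            if n == 0:
                continue
            i = rng.integers(n)
            pts[i] = pts[n - 1]
            n -= 1
        if return_trajectory:
            trajectory[accepted] = n
        accepted += 1
    pattern = PointPattern(pts[:n].copy(), window)
    if return_trajectory:
        return pattern, trajectory[:accepted]
    return pattern


def gen_cluster_pattern(parent_intensity: float, offspring_mean: float,
                        offspring_sd: float, window: Window = DEFAULT_WINDOW,
                        seed=None) -> PointPattern:
    """Thomas cluster process: Poisson parents, Gaussian-displaced offspring.

    Parents are simulated in the window dilated by 4 offspring SDs so that
    clusters centred just outside still contribute points inside.
    """
    if parent_intensity <= 0 or offspring_mean <= 0 or offspring_sd <= 0:
        raise ValueError("all Thomas-process parameters must be positive")
    rng = np.random.default_rng(seed)
    pad = 4.0 * offspring_sd
    big = Window(window.x_min - pad, window.x_max + pad,
                 window.y_min - pad, window.y_max + pad)
    n_par = rng.poisson(parent_intensity * big.area)
    parents = np.column_stack([
        rng.uniform(big.x_min, big.x_max, n_par),
        rng.uniform(big.y_min, big.y_max, n_par),
    ])
    counts = rng.poisson(offspring_mean, n_par)
    if counts.sum() == 0:
        return PointPattern(np.empty((0, 2)), window)
    centres = np.repeat(parents, counts, axis=0)
    xy = centres + rng.normal(0.0, offspring_sd, centres.shape)
    xy = xy[window.contains(xy)]
    return PointPattern(xy, window)


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

def gen_histology_image(pattern: PointPattern, nucleus_radius: float = 4.0,
                        px_per_um: float = 1.0,
                        stain_color=(64, 32, 96),
                        background_color=(235, 210, 225),
                        noise_sd: float = 0.0, seed=None):
    """Render a point pattern as a stained-nuclei-like RGB image.

    Each point becomes a filled disk of ``nucleus_radius`` um in the stain
    colour on the background colour, with optional additive Gaussian pixel
    noise.  Pixel (row, col) covers the square whose centre is at
    x = x_min + (col + 0.5)/px_per_um, y = y_max - (row + 0.5)/px_per_um
    (row 0 is the top of the image).

    Returns
    -------
    image : uint8 ndarray of shape (H, W, 3)
    truth : float ndarray (n, 2) - the ground-truth centres in um.
    """
    if nucleus_radius <= 0:
        raise ValueError("nucleus_radius must be positive")
    w = pattern.window
    W = int(round(w.width * px_per_um))
    H = int(round(w.height * px_per_um))
    img = np.empty((H, W, 3), dtype=float)
    img[:] = np.asarray(background_color, dtype=float)

    r_px = nucleus_radius * px_per_um
    stain = np.asarray(stain_color, dtype=float)
    for x, y in pattern.points:
        col_c = (x - w.x_min) * px_per_um - 0.5
        row_c = (w.y_max - y) * px_per_um - 0.5
        r0 = max(0, int(np.floor(row_c - r_px)))
        r1 = min(H, int(np.ceil(row_c + r_px)) + 1)
        c0 = max(0, int(np.floor(col_c - r_px)))
        c1 = min(W, int(np.ceil(col_c + r_px)) + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        disk = (rows - row_c) ** 2 + (cols - col_c) ** 2 <= r_px ** 2
        img[r0:r1, c0:c1][disk] = stain

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, pattern.points.copy()


# --------------------------------------------------------------------------
# cohort and counts
# --------------------------------------------------------------------------

def gen_cohort(spec: CohortSpec, with_patterns: bool = True):
    """Two-phenotype cohort bundle.

    Returns ``(patterns, table)`` where ``patterns`` maps patient_id to a
    PointPattern and ``table`` is a DataFrame with columns
    patient_id, survival_days, event, phenotype.  Gibbs-phenotype patients
    get hard-core patterns and long exponential survival; Invasion-phenotype
    patients get Thomas patterns and short survival.  A uniformly chosen
    ``censor_fraction`` of patients is right-censored at a uniform fraction
    of their true survival time.  ``with_patterns=False`` skips pattern
    simulation (patterns dict empty) while keeping the survival table
    identical — useful for survival-only experiments.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    patterns = {}
    phenos = ["Gibbs"] * spec.n_gibbs + ["Invasion"] * spec.n_invasion
    for i, pheno in enumerate(phenos):
        pid = f"P{i:04d}"
        sub = int(rng.integers(2 ** 31))
        pat = None
        if pheno == "Gibbs":
            ghet = spec.gibbs_heterogeneity
            gjit = rng.uniform(1.0 - ghet, 1.0 + ghet, size=2)
            if with_patterns:
                bd = BirthDeathParams(
                    birth_rate=spec.gibbs_intensity * gjit[0],
                    death_rate=1.0,
                    hard_core=spec.gibbs_hard_core * gjit[1], seed=sub)
                pat = gen_hardcore_pattern(bd, spec.window)
            scale = spec.survival_scale_gibbs
        else:
            het = spec.invasion_heterogeneity
            jitter = rng.uniform(1.0 - het, 1.0 + het, size=2)
            if with_patterns:
                pat = gen_cluster_pattern(
                    spec.invasion_parent_intensity,
                    spec.invasion_offspring_mean * jitter[0],
                    spec.invasion_offspring_sd * jitter[1],
                    spec.window, seed=sub)
            scale = spec.survival_scale_invasion
        t = rng.exponential(scale)
        censored = rng.random() < spec.censor_fraction
        if censored:
            t = t * rng.uniform(0.0, 1.0)
        t = max(t, 1e-3)  # survival strictly positive
        if pat is not None:
            patterns[pid] = pat
        rows.append({
            "patient_id": pid,
            "survival_days": float(t),
            "event": 0 if censored else 1,
            "phenotype": pheno,
        })
    table = pd.DataFrame(rows)
    return patterns, table


def gen_counts(spec: CountsSpec):
    """Negative-binomial count matrix with planted differential expression.

    Returns ``(counts, groups, truth)``: a genes x samples DataFrame of raw
    counts, a Series mapping sample id to group label ('LH-CIL' for group A,
    'H-CIL' for group B), and the list of planted DE gene ids, whose mean is
    multiplied by ``2**log2_effect`` in group B (H-CIL).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples_a + spec.n_samples_b
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    samples = ([f"A{i:03d}" for i in range(spec.n_samples_a)]
               + [f"B{i:03d}" for i in range(spec.n_samples_b)])
    groups = pd.Series(
        ["LH-CIL"] * spec.n_samples_a + ["H-CIL"] * spec.n_samples_b,
        index=samples, name="group")

    # gene baselines: log-normal spread around the nominal mean
    base = spec.baseline_mean * rng.lognormal(0.0, 1.0, spec.n_genes)
    lib = rng.uniform(0.5, 2.0, n)  # library-size factors

    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False) if n_de else \
        np.array([], dtype=int)
    mu = base[:, None] * lib[None, :]
    if n_de:
        b_cols = np.arange(spec.n_samples_a, n)
        mu[np.ix_(de_idx, b_cols)] *= 2.0 ** spec.log2_effect

    # NB parameterised by size = 1/dispersion, p = size/(size+mu)
    size = 1.0 / spec.dispersion
    counts = rng.negative_binomial(size, size / (size + mu))
    df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = [genes[i] for i in sorted(de_idx)]
    return df, groups, truth
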