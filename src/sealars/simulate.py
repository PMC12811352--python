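"""Synthetic telemetry, seascapes, and habitat-driven behavioural states.

Every input the analysis pipeline needs can be generated here: GPS-like fix
tables, 2-h dive/haulout summaries, haulout events, data gaps, and a gridded
seascape with categorical geomorphology and substrate, region labels and a
continuous stratification field (potential energy anomaly, J/m^3).

Tracks are simulated from the movement HMM itself: a Markov chain over
behavioural states, Gamma step lengths and wrapped-Cauchy turn angles per
state, positions by dead reckoning in planar km. Default parameter sets
(:data:`GREY_PROFILE`, :data:`HARBOUR_PROFILE`) are the fitted values for
grey and harbour seals in the southern North Sea study this package
re-implements: mean (SD) step lengths of 0.09 (0.09), 3.38 (1.76) and
7.63 (2.18) km per 2-h interval for grey-seal focussed ARS, broad ARS and
transit, with angle concentrations 0.07, 0.53 and 0.81, and 0.07 (0.06),
2.70 (1.50), 6.41 (2.19) km with concentrations 0.005, 0.46 and 0.76 for
harbour seals. Movement-state transition rows combine the reported
switching probabilities with self-transitions as row complements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, special

from .hmm import HMMParameters, KNOWN_STATES

__all__ = [
    "SimulationConfig",
    "SimulatedTrack",
    "SeascapeGrid",
    "HabitatCoefficients",
    "species_profile",
    "simulate_hmm_tracks",
    "build_seascape",
    "simulate_habitat_driven_states",
    "write_track_tables",
    "GREY_PROFILE",
    "HARBOUR_PROFILE",
]

#: dive-proportion threshold below which an interval is known non-diving
DIVE_THRESHOLD = 0.444
#: physiological maximum proportion of a 2-h interval spent diving
MAX_DIVE_PROP = 0.888

GEOMORPHOLOGY_CLASSES = ("peak", "steep_slope", "gradual_slope", "trough")
SUBSTRATE_CLASSES = ("sand", "gravel", "rock_reef", "mud")
DEFAULT_REGIONS = ("Orkney", "Moray Firth", "East UK", "Southeast UK",
                   "Dutch Delta", "Wadden Sea")

# movement-state parameters: (fARS, bARS, Tr)
_MOVE = {
    "grey": {
        "mu": (0.09, 3.38, 7.63),
        "sigma": (0.09, 1.76, 2.18),
        "angle_conc": (0.07, 0.53, 0.81),
        # rows: fARS, bARS, Tr; self-transitions are row complements of the
        # reported switching probabilities
        "tpm": [[0.835, 0.16, 0.005],
                [0.10, 0.82, 0.08],
                [0.004, 0.14, 0.856]],
    },
    "harbour": {
        "mu": (0.07, 2.70, 6.41),
        "sigma": (0.06, 1.50, 2.19),
        "angle_conc": (0.005, 0.46, 0.76),
        "tpm": [[0.77, 0.21, 0.02],
                [0.13, 0.77, 0.10],
                [0.03, 0.25, 0.72]],
    },
}

# non-diving state emission defaults: slow residual drift around the haulout
# or surface position, with a point mass of exactly-zero displacements
_N_STATE = {"mu": 0.25, "sigma": 0.20, "angle_conc": 0.02, "zero_mass": 0.25}

# probability of leaving a movement state for N / Unk in the 5-state chain;
# the published movement block is rescaled by the complement so rows sum to 1
_P_MOVE_TO_N = 0.06
_P_MOVE_TO_UNK = 0.02
_N_ROW = (0.02, 0.05, 0.08, 0.80, 0.05)
_UNK_ROW = (0.05, 0.10, 0.15, 0.20, 0.50)


def species_profile(species: str, movement_states_only: bool = True) -> HMMParameters:
    """HMM parameter set for ``grey`` or ``harbour`` seals.

    With ``movement_states_only`` the chain has the three movement states
    (fARS, bARS, Tr) with the published transition block. Otherwise the full
    five-state chain (adding N and Unk) is assembled; the rows and columns
    involving N and Unk are not published and use package defaults.
    """
    if species not in _MOVE:
        raise ValueError(f"unknown species {species!r}; expected 'grey' or 'harbour'")
    m = _MOVE[species]
    if movement_states_only:
        tpm = np.asarray(m["tpm"], dtype=float)
        p = HMMParameters(
            states=("fARS", "bARS", "Tr"),
            mu=m["mu"], sigma=m["sigma"], angle_conc=m["angle_conc"],
            tpm=tpm, delta=np.full(3, 1 / 3),
        )
    else:
        move = np.asarray(m["tpm"], dtype=float) * (1 - _P_MOVE_TO_N - _P_MOVE_TO_UNK)
        tpm = np.zeros((5, 5))
        tpm[:3, :3] = move
        tpm[:3, 3] = _P_MOVE_TO_N
        tpm[:3, 4] = _P_MOVE_TO_UNK
        tpm[3] = _N_ROW
        tpm[4] = _UNK_ROW
        p = HMMParameters(
            states=("fARS", "bARS", "Tr", "N", "Unk"),
            mu=list(m["mu"]) + [_N_STATE["mu"]],
            sigma=list(m["sigma"]) + [_N_STATE["sigma"]],
            angle_conc=list(m["angle_conc"]) + [_N_STATE["angle_conc"]],
            zero_mass=[0.0, 0.0, 0.0, _N_STATE["zero_mass"]],
            tpm=tpm, delta=np.full(5, 0.2),
        )
    import dataclasses
    return dataclasses.replace(p, delta=p.stationary())


GREY_PROFILE = species_profile("grey", movement_states_only=False)
HARBOUR_PROFILE = species_profile("harbour", movement_states_only=False)


def merged_ars_profile(species: str = "grey") -> HMMParameters:
    """Four-state generating chain with a single (merged) ARS state.

    Used to exercise order selection in the direction where one ARS scale is
    the truth. The ARS emission sits between the species' focussed and broad
    ARS distributions; transit and the non-diving state keep the species
    values.
    """
    m = _MOVE[species]
    import dataclasses
    p = HMMParameters(
        states=("ARS", "Tr", "N", "Unk"),
        mu=[0.5 * (m["mu"][0] + m["mu"][1]), m["mu"][2], _N_STATE["mu"]],
        sigma=[0.5 * (m["sigma"][0] + m["sigma"][1]), m["sigma"][2], _N_STATE["sigma"]],
        angle_conc=[0.5 * (m["angle_conc"][0] + m["angle_conc"][1]),
                    m["angle_conc"][2], _N_STATE["angle_conc"]],
        zero_mass=[0.0, 0.0, _N_STATE["zero_mass"]],
        tpm=[[0.84, 0.08, 0.06, 0.02],
             [0.14, 0.78, 0.06, 0.02],
             [0.07, 0.08, 0.80, 0.05],
             [0.15, 0.15, 0.20, 0.50]],
        delta=np.full(4, 0.25),
    )
    return dataclasses.replace(p, delta=p.stationary())


@dataclass
class SimulationConfig:
    """Study conditions for track simulation.

    Step lengths are km per 2-h interval; positions are planar km.
    """

    n_individuals: int = 10
    n_intervals_per_individual: int = 500
    species_profile: str = "grey"
    movement_states_only: bool = True
    gap_rate: float = 0.0
    seed: int = 0
    step_units: str = "km per 2-h interval"
    start_time: str = "2018-06-01 01:00:00"

    def __post_init__(self):
        if self.n_individuals <= 0 or self.n_intervals_per_individual <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must lie in [0, 1)")


@dataclass
class SimulatedTrack:
    """One individual's simulated 2-h interval series with ground truth."""

    individual: str
    data: pd.DataFrame          # timestamp, state, x, y, step, angle, prop_diving, gap
    haulout_events: pd.DataFrame


def _draw_steps(rng, params: HMMParameters, z: np.ndarray) -> np.ndarray:
    steps = np.empty(len(z))
    for s in range(params.n_emitting):
        sel = z == s
        if not sel.any():
            continue
        mu, sig = params.mu[s], params.sigma[s]
        shape, scale = mu * mu / (sig * sig), sig * sig / mu
        vals = rng.gamma(shape, scale, size=int(sel.sum()))
        zm = params.zero_mass[s]
        if zm > 0:
            vals = np.where(rng.random(len(vals)) < zm, 0.0, vals)
        steps[sel] = vals
    return steps


def _draw_angles(rng, params: HMMParameters, z: np.ndarray) -> np.ndarray:
    """Wrapped Cauchy draws: wrap a linear Cauchy with scale -log(conc)."""
    angles = np.empty(len(z))
    for s in range(params.n_emitting):
        sel = z == s
        if not sel.any():
            continue
        conc = params.angle_conc[s]
        n = int(sel.sum())
        if conc <= 0:
            a = rng.uniform(-np.pi, np.pi, size=n)
        else:
            a = np.mod(rng.standard_cauchy(n) * (-np.log(conc)) + np.pi,
                       2 * np.pi) - np.pi
        angles[sel] = a
    return angles


def simulate_hmm_tracks(config: SimulationConfig,
                        params: HMMParameters | None = None) -> list[SimulatedTrack]:
    """Simulate 2-h regularised tracks from the movement HMM.

    State sequences follow the Markov chain (initial state from the
    stationary distribution); given the state, steps are Gamma and turn
    angles wrapped Cauchy; positions are built by dead reckoning from steps
    and cumulative headings. Dive proportions are drawn from scaled Beta
    distributions above the 0.444 threshold for movement states and below it
    for the non-diving state. Gap intervals (rate ``config.gap_rate``, plus
    every interval spent in ``Unk``) lose their position and summary fields.
    """
    if params is None:
        params = species_profile(config.species_profile, config.movement_states_only)
    params.validate()
    rng = np.random.default_rng(config.seed)
    state_names = np.asarray(params.states, dtype=object)
    unk_idx = params.states.index("Unk") if "Unk" in params.states else -1
    n_idx = params.states.index("N") if "N" in params.states else -1
    delta, tpm = params.delta, params.tpm
    K = params.n_states
    tracks = []
    times = pd.date_range(config.start_time, periods=config.n_intervals_per_individual,
                          freq="2h")
    for i in range(config.n_individuals):
        T = config.n_intervals_per_individual
        z = np.empty(T, dtype=int)
        z[0] = rng.choice(K, p=delta)
        u = rng.random(T)
        cum = np.cumsum(tpm, axis=1)
        for t in range(1, T):
            z[t] = np.searchsorted(cum[z[t - 1]], u[t], side="right")
        emit = np.where(z < params.n_emitting, z, -1)
        steps = np.where(emit >= 0, _draw_steps(rng, params, np.clip(emit, 0, None)), np.nan)
        turns = np.where(emit >= 0, _draw_angles(rng, params, np.clip(emit, 0, None)), np.nan)
        heading = np.cumsum(np.where(np.isnan(turns), 0.0, turns)) + rng.uniform(0, 2 * np.pi)
        dx = np.where(np.isnan(steps), 0.0, steps) * np.cos(heading)
        dy = np.where(np.isnan(steps), 0.0, steps) * np.sin(heading)
        x = np.concatenate([[0.0], np.cumsum(dx)])[:-1]
        y = np.concatenate([[0.0], np.cumsum(dy)])[:-1]
        # dive proportions: movement states dive most of the interval,
        # the non-diving state less than the 0.444 cutoff
        beta = rng.beta(2.0, 2.0, size=T)
        prop = np.where(z == n_idx, DIVE_THRESHOLD * beta,
                        DIVE_THRESHOLD + (MAX_DIVE_PROP - DIVE_THRESHOLD) * beta)
        gap = rng.random(T) < config.gap_rate
        if unk_idx >= 0:
            gap |= z == unk_idx
        df = pd.DataFrame({
            "individual": f"ind{i:03d}",
            "timestamp": times,
            "state": state_names[z],
            "x": np.where(gap, np.nan, x),
            "y": np.where(gap, np.nan, y),
            "step": np.where(gap, np.nan, steps),
            "angle": np.where(gap, np.nan, turns),
            "prop_diving": np.where(gap, np.nan, prop),
            "gap": gap,
        })
        df.loc[df["gap"], "state"] = "Unk" if unk_idx >= 0 else df.loc[df["gap"], "state"]
        tracks.append(SimulatedTrack(f"ind{i:03d}", df, _haulout_events(df, n_idx >= 0)))
    return tracks


def _haulout_events(df: pd.DataFrame, has_n: bool) -> pd.DataFrame:
    """Runs of >= 2 consecutive non-diving intervals become haulout events."""
    rows = []
    if has_n:
        is_n = (df["state"] == "N").to_numpy()
        t = df["timestamp"].to_numpy()
        start = None
        for k in range(len(df) + 1):
            if k < len(df) and is_n[k]:
                if start is None:
                    start = k
            else:
                if start is not None and k - start >= 2:
                    rows.append({
                        "individual": df["individual"].iloc[0],
                        "start": t[start] - np.timedelta64(1, "h"),
                        "end": t[k - 1] + np.timedelta64(1, "h"),
                        "x": df["x"].iloc[start], "y": df["y"].iloc[start],
                    })
                start = None
    return pd.DataFrame(rows, columns=["individual", "start", "end", "x", "y"])


def tracks_to_intervals(tracks: list[SimulatedTrack]) -> pd.DataFrame:
    """Stack tracks into the interval table the HMM module consumes.

    Known-state codes follow the a-priori rule: gaps are ``Unk``, dive
    proportion below 0.444 is ``N`` (only meaningful when the generating
    chain has those states), everything else is free.
    """
    frames = []
    for tr in tracks:
        d = tr.data.copy()
        has_n = (d["state"] == "N").any() or (d["state"] == "Unk").any()
        if has_n:
            code = np.where(d["gap"], "Unk",
                            np.where(d["prop_diving"] < DIVE_THRESHOLD, "N", "free"))
        else:
            code = np.where(d["gap"], "Unk", "free")
        d["known_state"] = code
        frames.append(d)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# seascape
# --------------------------------------------------------------------------


@dataclass
class SeascapeGrid:
    """Gridded seascape: categorical layers, regions, PEA, haulout sites.

    ``x0``/``y0`` are the lower-left corner; cell ``(r, c)`` covers
    ``[x0 + c*cell, x0 + (c+1)*cell) x [y0 + r*cell, ...)`` in km.
    """

    x0: float
    y0: float
    cell: float
    geomorphology: np.ndarray   # int codes into GEOMORPHOLOGY_CLASSES
    substrate: np.ndarray       # int codes into SUBSTRATE_CLASSES
    region: np.ndarray          # int codes into region_names
    pea: np.ndarray             # J/m^3, >= 0
    region_names: tuple = DEFAULT_REGIONS
    haulout_sites: pd.DataFrame = None  # x, y, region

    @property
    def shape(self):
        return self.pea.shape

    def _cell_index(self, x, y):
        c = np.floor((np.asarray(x, dtype=float) - self.x0) / self.cell).astype(int)
        r = np.floor((np.asarray(y, dtype=float) - self.y0) / self.cell).astype(int)
        nr, nc = self.shape
        return np.clip(r, 0, nr - 1), np.clip(c, 0, nc - 1)

    def value_at(self, x, y, layer: str):
        """Nearest-cell lookup of a layer at planar coordinates (km)."""
        r, c = self._cell_index(x, y)
        arr = getattr(self, layer)
        return arr[r, c]

    def lookup(self, x, y) -> pd.DataFrame:
        r, c = self._cell_index(x, y)
        return pd.DataFrame({
            "geomorphology": np.asarray(GEOMORPHOLOGY_CLASSES, dtype=object)[self.geomorphology[r, c]],
            "substrate": np.asarray(SUBSTRATE_CLASSES, dtype=object)[self.substrate[r, c]],
            "region": np.asarray(self.region_names, dtype=object)[self.region[r, c]],
            "pea": self.pea[r, c],
        })

    def write(self, directory):
        """Write the grid as plain-text rasters plus a JSON legend sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("geomorphology", "substrate", "region"):
            np.savetxt(directory / f"{name}.csv", getattr(self, name), fmt="%d",
                       delimiter=",")
        np.savetxt(directory / "pea.csv", self.pea, fmt="%.6g", delimiter=",")
        legend = {
            "x0": self.x0, "y0": self.y0, "cell": self.cell,
            "geomorphology": list(GEOMORPHOLOGY_CLASSES),
            "substrate": list(SUBSTRATE_CLASSES),
            "region": list(self.region_names),
        }
        (directory / "legend.json").write_text(json.dumps(legend, indent=1))
        if self.haulout_sites is not None:
            self.haulout_sites.to_csv(directory / "haulout_sites.csv", index=False)

    @classmethod
    def read(cls, directory) -> "SeascapeGrid":
        directory = Path(directory)
        legend = json.loads((directory / "legend.json").read_text())
        sites = directory / "haulout_sites.csv"
        return cls(
            x0=legend["x0"], y0=legend["y0"], cell=legend["cell"],
            geomorphology=np.loadtxt(directory / "geomorphology.csv", dtype=int,
                                     delimiter=",", ndmin=2),
            substrate=np.loadtxt(directory / "substrate.csv", dtype=int,
                                 delimiter=",", ndmin=2),
            region=np.loadtxt(directory / "region.csv", dtype=int, delimiter=",",
                              ndmin=2),
            pea=np.loadtxt(directory / "pea.csv", delimiter=",", ndmin=2),
            region_names=tuple(legend["region"]),
            haulout_sites=pd.read_csv(sites) if sites.exists() else None,
        )


def _smooth_field(rng, shape, smooth=6.0):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), smooth, mode="reflect")
    return (f - f.mean()) / (f.std() + 1e-12)


def build_seascape(extent=(0.0, 0.0, 200.0, 120.0), n_regions: int = 6,
                   seed: int = 0, cell: float = 2.0) -> SeascapeGrid:
    """Generate a synthetic gridded seascape.

    Smooth Gaussian random fields are thresholded at quantiles into
    categorical geomorphology and substrate patches; PEA is a smooth
    non-negative surface (softplus of a random field, scaled to a realistic
    0-40 J/m^3 range); regions are contiguous vertical bands, each with one
    haulout site.
    """
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent is degenerate")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    nc = max(int(round((x1 - x0) / cell)), n_regions)
    nr = max(int(round((y1 - y0) / cell)), 2)
    shape = (nr, nc)

    def categorise(field, n_classes):
        qs = np.quantile(field, np.linspace(0, 1, n_classes + 1)[1:-1])
        return np.searchsorted(qs, field.ravel()).reshape(shape)

    geo = categorise(_smooth_field(rng, shape), len(GEOMORPHOLOGY_CLASSES))
    sub = categorise(_smooth_field(rng, shape), len(SUBSTRATE_CLASSES))
    pea = 12.0 * np.log1p(np.exp(2.0 * _smooth_field(rng, shape, smooth=10.0)))
    region = np.repeat(
        np.minimum(np.arange(nc) * n_regions // nc, n_regions - 1)[None, :], nr, axis=0)
    names = (DEFAULT_REGIONS if n_regions == len(DEFAULT_REGIONS)
             else tuple(f"region_{k + 1}" for k in range(n_regions)))
    sites = []
    for k in range(n_regions):
        cols = np.where(region[0] == k)[0]
        c = rng.choice(cols)
        r = rng.integers(0, nr)
        sites.append({"x": x0 + (c + 0.5) * cell, "y": y0 + (r + 0.5) * cell,
                      "region": names[k]})
    return SeascapeGrid(x0=x0, y0=y0, cell=cell, geomorphology=geo, substrate=sub,
                        region=region, pea=pea, region_names=names,
                        haulout_sites=pd.DataFrame(sites))


# --------------------------------------------------------------------------
# habitat-driven state simulation
# --------------------------------------------------------------------------


@dataclass
class HabitatCoefficients:
    """Logit-scale generating coefficients for the nested binomial models.

    ``ars`` parameterises logit P(ARS | encounter) and ``fars`` parameterises
    logit P(focussed ARS | ARS). Category effects are treatment-coded
    relative to the first class of each layer; ``pea_fn`` is an optional
    smooth effect of PEA on the linear predictor.
    """

    ars_intercept: float = 0.0
    fars_intercept: float = 0.0
    ars_effects: dict = field(default_factory=dict)   # {("geomorphology","trough"): 0.4, ...}
    fars_effects: dict = field(default_factory=dict)
    ars_pea_fn: object = None
    fars_pea_fn: object = None

    def linpred(self, which: str, rows: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(rows), self.ars_intercept if which == "ars" else self.fars_intercept)
        effects = self.ars_effects if which == "ars" else self.fars_effects
        for (layer, level), beta in effects.items():
            if not np.isfinite(beta):
                raise ValueError("coefficients must be finite")
            eta += beta * (rows[layer] == level).to_numpy()
        fn = self.ars_pea_fn if which == "ars" else self.fars_pea_fn
        if fn is not None:
            eta += fn(rows["pea"].to_numpy())
        return eta


def simulate_habitat_driven_states(
    seascape: SeascapeGrid,
    coefficients: HabitatCoefficients,
    random_intercept_sd: float = 0.5,
    n_individuals: int = 50,
    n_intervals: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate decoded movement-state intervals with habitat-driven switching.

    Each interval is dropped uniformly on the seascape, its habitat cell
    looked up, and its state drawn by two nested Bernoulli draws: ARS versus
    transit with probability ``expit(eta_ars + b_i)``, then focussed versus
    broad ARS with probability ``expit(eta_fars + c_i)``, with per-individual
    Normal(0, sd^2) random intercepts ``b_i``, ``c_i``. The generating
    probabilities (at the individual's own intercept) are stored alongside
    for recovery tests.
    """
    rng = np.random.default_rng(seed)
    n = n_individuals * n_intervals
    nr, ncols = seascape.shape
    x = seascape.x0 + rng.uniform(0, ncols * seascape.cell, size=n)
    y = seascape.y0 + rng.uniform(0, nr * seascape.cell, size=n)
    rows = seascape.lookup(x, y)
    rows.insert(0, "individual",
                np.repeat([f"ind{i:03d}" for i in range(n_individuals)], n_intervals))
    b = rng.normal(0, random_intercept_sd, size=n_individuals)
    c = rng.normal(0, random_intercept_sd, size=n_individuals)
    b_row = np.repeat(b, n_intervals)
    c_row = np.repeat(c, n_intervals)
    p_ars = special.expit(coefficients.linpred("ars", rows) + b_row)
    p_fars = special.expit(coefficients.linpred("fars", rows) + c_row)
    is_ars = rng.random(n) < p_ars
    is_fars = rng.random(n) < p_fars
    state = np.where(is_ars, np.where(is_fars, "fARS", "bARS"), "Tr")
    rows["state"] = state
    rows["p_ars_true"] = p_ars
    rows["p_fars_true"] = p_fars
    rows["x"] = x
    rows["y"] = y
    return rows


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------


def write_track_tables(tracks: list[SimulatedTrack], directory) -> dict:
    """Write fixes / summaries / haulout-event / true-state CSVs.

    Fixes are emitted at the interval midpoints with plausible satellite
    counts and residual-error scores; true states go to a separate file used
    only by tests.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fixes, summaries, haulouts, truth = [], [], [], []
    for tr in tracks:
        d = tr.data
        ok = ~d["gap"]
        fixes.append(pd.DataFrame({
            "individual": d.loc[ok, "individual"],
            "timestamp": d.loc[ok, "timestamp"],
            "x_km": d.loc[ok, "x"], "y_km": d.loc[ok, "y"],
            "n_satellites": 7, "residual": 5.0,
        }))
        summaries.append(pd.DataFrame({
            "individual": d["individual"],
            "interval_start": d["timestamp"] - pd.Timedelta(hours=1),
            "interval_end": d["timestamp"] + pd.Timedelta(hours=1),
            "prop_diving": d["prop_diving"],
            "prop_hauled": np.where(d["state"] == "N", 0.5, 0.0),
        }))
        haulouts.append(tr.haulout_events)
        truth.append(d[["individual", "timestamp", "state"]])
    paths = {}
    for name, frames in (("fixes", fixes), ("summaries", summaries),
                         ("haulout_events", haulouts), ("true_states", truth)):
        nonempty = [f for f in frames if len(f)]
        out = pd.concat(nonempty, ignore_index=True) if nonempty else frames[0]
        paths[name] = directory / f"{name}.csv"
        out.to_csv(paths[name], index=False)
    return paths
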