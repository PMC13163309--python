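"""Seeded synthetic-data generators and packaged worked-example tables.

Every generator is a pure function of a :class:`SimConfig`: the same config
(including its ``seed``) yields bit-identical output on every call.  The
generators emulate the four input classes the downstream stages consume —

* two-condition negative-binomial RNA-seq counts with planted differentially
  expressed genes,
* two-class log-normal metabolite intensity tables with planted discriminant
  features,
* STRING-style weighted edge lists from an Erdős–Rényi background with
  explicitly wired high-degree hubs,
* CCK-8 microplate absorbances generated from four-parameter-logistic
  dose–response curves with known IC50.

Ground truth for each simulation is returned as a :class:`TruthLabels` record
so recovery rates (sensitivity, empirical FDR, hub ranking) can be measured
downstream.  The module also loads the two packaged worked-example tables
(top-20 prioritized genes; per-target docking results), checksum-verified and
transcribed digit-for-digit from the published report.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, FixtureError

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: CCK-8 assay concentrations (µM) used for the plate layout.
PLATE_CONCENTRATIONS_UM = (0.03, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass(frozen=True)
class FourPLParams:
    """True four-parameter-logistic curve for one compound.

    ``viability(x) = bottom + (top - bottom) / (1 + (x / ic50) ** hill)``
    with ``x`` in µM and viability in percent.
    """

    bottom: float = 0.0
    top: float = 100.0
    hill: float = 1.0
    ic50: float = 1.0

    def viability(self, conc_um: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(conc_um, dtype=float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (x / self.ic50) ** self.hill)


def _default_plate_params() -> dict[str, FourPLParams]:
    # Four assayed compounds; true IC50s set to the reported potencies (µM).
    return {
        "Amino(1H-indol-2-yl)acetic acid": FourPLParams(ic50=0.2397),
        "Lactol": FourPLParams(ic50=1.226),
        'Quercetin 3-(6"-malonyl-glucoside)': FourPLParams(ic50=1.301),
        "Doxorubicin": FourPLParams(ic50=1.306),
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for all four generators.

    Defaults are desk-scale: 2,000 genes x 3+3 samples, 500 metabolite
    features, a 60-node interaction graph, and a 96-well-style plate with two
    biological and three technical replicates.
    """

    seed: int = 0
    # RNA-seq counts
    n_genes: int = 2000
    n_per_group: int = 3
    frac_de: float = 0.05
    lfc_magnitude: float = 1.5
    nb_dispersion: float = 0.02
    # metabolite table
    n_features_metab: int = 500
    frac_discriminant: float = 0.05
    metab_effect: float = 5.0
    metab_sigma: float = 0.1
    # interaction graph
    graph_n_nodes: int = 60
    graph_edge_prob: float = 0.05
    planted_hub_count: int = 3
    hub_degree_factor: float = 4.0
    # plate
    plate_true_params: Mapping[str, FourPLParams] = field(default_factory=_default_plate_params)
    plate_concentrations_um: tuple[float, ...] = PLATE_CONCENTRATIONS_UM
    plate_noise_pct: float = 3.0
    n_bio_reps: int = 2
    n_tech_reps: int = 3

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_per_group": self.n_per_group,
            "n_features_metab": self.n_features_metab,
            "graph_n_nodes": self.graph_n_nodes,
            "n_bio_reps": self.n_bio_reps,
            "n_tech_reps": self.n_tech_reps,
        }
        for name, value in counts.items():
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigError(f"{name} must be a count >= 1, got {value!r}")
        fractions = {
            "frac_de": self.frac_de,
            "frac_discriminant": self.frac_discriminant,
            "graph_edge_prob": self.graph_edge_prob,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be positive, got {self.nb_dispersion!r}")
        if self.lfc_magnitude < 0:
            raise ConfigError(f"lfc_magnitude must be >= 0, got {self.lfc_magnitude!r}")
        if self.metab_effect <= 0:
            raise ConfigError(f"metab_effect must be positive, got {self.metab_effect!r}")
        if self.metab_sigma < 0:
            raise ConfigError(f"metab_sigma must be >= 0, got {self.metab_sigma!r}")
        if self.planted_hub_count < 0:
            raise ConfigError(f"planted_hub_count must be >= 0, got {self.planted_hub_count!r}")
        if self.planted_hub_count > self.graph_n_nodes:
            raise ConfigError("planted_hub_count cannot exceed graph_n_nodes")
        if self.plate_noise_pct < 0:
            raise ConfigError(f"plate_noise_pct must be >= 0, got {self.plate_noise_pct!r}")
        if any(c <= 0 for c in self.plate_concentrations_um):
            raise ConfigError("plate_concentrations_um must all be positive")
        for compound, params in self.plate_true_params.items():
            if not isinstance(params, FourPLParams) or params.ic50 <= 0:
                raise ConfigError(f"plate_true_params[{compound!r}] must be a FourPLParams with ic50 > 0")

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "SimConfig":
        """Load a config from a TOML or YAML file, optionally overriding the seed."""
        path = Path(path)
        if path.suffix in {".toml", ".tml"}:
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            import yaml

            raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        if "plate_true_params" in raw:
            raw["plate_true_params"] = {
                name: FourPLParams(**params) for name, params in raw["plate_true_params"].items()
            }
        if seed is not None:
            raw["seed"] = seed
        try:
            return cls(**raw)
        except TypeError as exc:  # unknown field
            raise ConfigError(str(exc)) from exc


@dataclass
class TruthLabels:
    """Planted ground truth attached to each simulated dataset."""

    de_gene_ids: set[str] = field(default_factory=set)
    true_lfc: pd.Series | None = None
    discriminant_feature_ids: set[str] = field(default_factory=set)
    hub_node_ids: set[str] = field(default_factory=set)
    true_ic50: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.Series, TruthLabels]:
    """Two-condition negative-binomial count matrix with planted DE genes.

    Gene-wise baseline means are log-normal across genes; the dispersion is
    shared (gamma–Poisson mixture).  Exactly ``round(frac_de * n_genes)``
    genes carry a mean shift of ``±lfc_magnitude`` log2 units in the treated
    group, with random sign.

    Returns ``(counts, lengths, truth)``: counts is genes x samples with
    columns ``control_1.. treated_1..``, lengths is per-gene transcript
    length in bp, and truth carries the planted gene ids and true log2 fold
    changes.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.n_per_group
    gene_ids = [f"gene_{i:05d}" for i in range(n)]

    base_mean = rng.lognormal(mean=math.log(80.0), sigma=1.2, size=n)
    n_de = round(config.frac_de * n)
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    true_lfc = np.zeros(n)
    if n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        true_lfc[de_idx] = signs * config.lfc_magnitude

    mean_ctrl = np.repeat(base_mean[:, None], m, axis=1)
    mean_trt = np.repeat((base_mean * 2.0 ** true_lfc)[:, None], m, axis=1)
    means = np.hstack([mean_ctrl, mean_trt])

    shape = 1.0 / config.nb_dispersion
    counts = rng.poisson(rng.gamma(shape, means / shape))

    columns = [f"control_{j + 1}" for j in range(m)] + [f"treated_{j + 1}" for j in range(m)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=columns)
    lengths = pd.Series(rng.integers(200, 10001, size=n), index=gene_ids, name="length_bp")

    truth = TruthLabels(
        de_gene_ids={gene_ids[i] for i in de_idx},
        true_lfc=pd.Series(true_lfc, index=gene_ids, name="true_lfc"),
    )
    return counts_df, lengths, truth


def group_labels(config: SimConfig) -> list[str]:
    """Sample group labels matching the column order of simulate_counts."""
    return ["control"] * config.n_per_group + ["treated"] * config.n_per_group


# ---------------------------------------------------------------------------
# Metabolite feature table
# ---------------------------------------------------------------------------

def simulate_metabolite_table(config: SimConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Two-class log-normal metabolite intensities with planted class effects.

    The class effect is multiplicative (treated mean = ``metab_effect`` x
    control mean for planted features), so the raw-scale fold change is
    directly interpretable.  Returns a features x columns frame with ``mz``
    and ``rt`` metadata columns followed by the sample columns.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, m = config.n_features_metab, config.n_per_group
    feature_ids = [f"feat_{i:05d}" for i in range(n)]

    base = rng.lognormal(mean=math.log(1e6), sigma=1.0, size=n)
    n_disc = round(config.frac_discriminant * n)
    disc_idx = rng.choice(n, size=n_disc, replace=False) if n_disc else np.array([], dtype=int)
    effect = np.ones(n)
    effect[disc_idx] = config.metab_effect

    noise = rng.normal(0.0, config.metab_sigma, size=(n, 2 * m))
    means = np.hstack([np.repeat(base[:, None], m, axis=1),
                       np.repeat((base * effect)[:, None], m, axis=1)])
    intensities = means * np.exp(noise)

    columns = [f"control_{j + 1}" for j in range(m)] + [f"treated_{j + 1}" for j in range(m)]
    df = pd.DataFrame(intensities, index=feature_ids, columns=columns)
    df.insert(0, "mz", rng.uniform(100.0, 1000.0, size=n))
    df.insert(1, "rt", rng.uniform(0.5, 12.0, size=n))
    df.index.name = "feature_id"

    truth = TruthLabels(discriminant_feature_ids={feature_ids[i] for i in disc_idx})
    return df, truth


# ---------------------------------------------------------------------------
# Interaction graph
# ---------------------------------------------------------------------------

def simulate_network(config: SimConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Weighted edge list: Erdős–Rényi background plus planted hubs.

    Hubs are wired to at least ``hub_degree_factor x edge_prob x (n - 1)``
    neighbours (factor defaults to 4, comfortably above the 2x floor the
    truth labels promise).  Edge weights are uniform on [0.4, 1.0] so a
    0.700 confidence threshold discards roughly half the edges.
    """
    rng = np.random.default_rng(config.seed + 2)
    n = config.graph_n_nodes
    node_ids = [f"prot_{i:04d}" for i in range(n)]

    adj = np.triu(rng.random((n, n)) < config.graph_edge_prob, k=1)

    hub_idx = (rng.choice(n, size=config.planted_hub_count, replace=False)
               if config.planted_hub_count else np.array([], dtype=int))
    background_deg = config.graph_edge_prob * (n - 1)
    target_deg = min(n - 1, math.ceil(config.hub_degree_factor * background_deg))
    sym = adj | adj.T
    for h in hub_idx:
        deficit = target_deg - int(sym[h].sum())
        if deficit > 0:
            candidates = np.flatnonzero(~sym[h])
            candidates = candidates[candidates != h]
            extra = rng.choice(candidates, size=min(deficit, len(candidates)), replace=False)
            for j in extra:
                a, b = min(h, j), max(h, j)
                adj[a, b] = True
            sym = adj | adj.T

    rows_a, rows_b = np.nonzero(adj)
    weights = rng.uniform(0.4, 1.0, size=len(rows_a))
    edges = pd.DataFrame({
        "node_a": [node_ids[i] for i in rows_a],
        "node_b": [node_ids[j] for j in rows_b],
        "combined_score": weights,
    })
    truth = TruthLabels(hub_node_ids={node_ids[i] for i in hub_idx})
    return edges, truth


# ---------------------------------------------------------------------------
# CCK-8 plate
# ---------------------------------------------------------------------------

#: Nominal optical densities of the untreated-control and blank wells.
CONTROL_OD = 1.10
BLANK_OD = 0.10


def simulate_plate(config: SimConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Microplate absorbance table from true 4PL curves plus Gaussian noise.

    For each compound, concentration, biological replicate and technical
    replicate a sample well is generated; each biological replicate also
    carries its own control and blank wells.  Noise is Gaussian with standard
    deviation ``plate_noise_pct`` percent of the control-minus-blank dynamic
    range (applied to sample and control wells; blanks get a tenth of it).
    """
    rng = np.random.default_rng(config.seed + 3)
    concs = np.asarray(config.plate_concentrations_um, dtype=float)
    span = CONTROL_OD - BLANK_OD
    sd = config.plate_noise_pct / 100.0 * span

    rows: list[dict] = []
    for bio in range(1, config.n_bio_reps + 1):
        for tech in range(1, config.n_tech_reps + 1):
            rows.append({"compound": "", "conc_uM": 0.0, "bio_rep": bio, "tech_rep": tech,
                         "absorbance": CONTROL_OD + rng.normal(0.0, sd),
                         "well_type": "control"})
            rows.append({"compound": "", "conc_uM": 0.0, "bio_rep": bio, "tech_rep": tech,
                         "absorbance": BLANK_OD + rng.normal(0.0, sd / 10.0),
                         "well_type": "blank"})
        for compound, params in config.plate_true_params.items():
            viab = params.viability(concs)
            for conc, v in zip(concs, viab):
                for tech in range(1, config.n_tech_reps + 1):
                    od = BLANK_OD + span * v / 100.0 + rng.normal(0.0, sd)
                    rows.append({"compound": compound, "conc_uM": float(conc),
                                 "bio_rep": bio, "tech_rep": tech,
                                 "absorbance": od, "well_type": "sample"})
    plate = pd.DataFrame(rows)
    truth = TruthLabels(true_ic50={c: p.ic50 for c, p in config.plate_true_params.items()})
    return plate, truth


# ---------------------------------------------------------------------------
# Packaged worked-example tables
# ---------------------------------------------------------------------------

_FIXTURE_SHA256 = {
    "table1": "7c6895b50a85e90b20119aeb91384e7c3836ac6dc978383c6b72b4b6b787b204",
    "table2": "00431d13ee5bc5675a20a0bb87c9712d6a4f624e97a7401b5cf5bfd490a11849",
}

# Typographic characters appearing in the source tables, mapped for the
# machine-readable key columns; display columns keep the originals.
_TYPOGRAPHY = str.maketrans({"−": "-", "′": "'", "″": '"'})


def _normalize_number(text: str) -> float:
    return float(str(text).translate(_TYPOGRAPHY).lstrip("+"))


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table fixture ('table1' or 'table2'), checksum-verified.

    ``table1`` holds the 20 prioritized genes (rank, gene, pathway, p_adjust,
    log2fc, fpkm, relevance, score).  ``table2`` holds 50 docking rows (10 per
    target across 5 targets) with docking score and MM-GBSA binding free
    energy.  Unicode minus signs are normalized to ASCII at parse time;
    compound names additionally get an ASCII ``compound_key`` with the
    original kept as the display name.
    """
    if name not in _FIXTURE_SHA256:
        raise FixtureError(f"unknown fixture {name!r}; expected 'table1' or 'table2'")
    try:
        raw = resources.files("netprio").joinpath(f"data/{name}.tsv").read_bytes()
    except (FileNotFoundError, ModuleNotFoundError) as exc:
        raise FixtureError(f"fixture {name} is missing from the package") from exc
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureError(f"fixture {name} failed its checksum ({digest})")

    from io import StringIO

    df = pd.read_csv(StringIO(raw.decode("utf-8")), sep="\t", dtype=str)
    if name == "table1":
        for col in ("p_adjust", "log2fc", "fpkm", "relevance", "score"):
            df[col] = df[col].map(_normalize_number)
        df["rank"] = df["rank"].astype(int)
    else:
        for col in ("mz", "rt_min", "docking_score", "dg_bind"):
            df[col] = df[col].map(_normalize_number)
        df["compound_key"] = df["compound_name"].str.translate(_TYPOGRAPHY)
    return df
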