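"""Toy metabolic models and simulated multi-omics datasets with known truth.

The generator emulates the structure of a chemostat multi-omics study of
*E. coli* central metabolism: a panel of samples spanning several
dilution-rate levels (here, glucose feed levels) plus a set of single-gene
knockout strains, each measured for transcript levels, protein abundances,
two input exchange fluxes (glucose and oxygen uptake) and a panel of
reference fluxes estimated independently of the model.

Ground-truth fluxes come from parsimonious FBA on a small branched network
with respiration, overflow secretion routes and a parallel pathway; omics
features are noisy monotone functions (saturating by default) of small flux
subsets. Reference fluxes can be perturbed *off* the steady-state solution
space along stoichiometric row-space directions, reproducing the conflict
between flux measurements and a genome-scale model's solution space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import cobra

from .gem_toolkit import (
    build_projection,
    net_flux_targets,
    stoichiometric_matrix,
)
from .cbm_solvers import solve_pfba

logger = logging.getLogger("minnflux")

__all__ = [
    "SyntheticSpec",
    "OmicsDataset",
    "make_toy_gem",
    "simulate_dataset",
    "write_omics_tables",
    "read_omics_tables",
    "GLC_UPTAKE",
    "O2_UPTAKE",
    "SECRETIONS",
]

#: directional reaction ids of the split toy model carrying measured inputs
GLC_UPTAKE = "EX_glc_rev"
O2_UPTAKE = "EX_o2_rev"
#: secretion exchange ids of the toy model (already forward-only)
SECRETIONS = ("EX_co2", "EX_ac", "EX_etoh")

#: a reference-flux panel over the toy network mirroring the structure of
#: the study's measured panel: central-metabolism reactions, secretion
#: exchanges and growth, disjoint from the measured input exchanges
TOY_REFERENCE_PANEL = (
    "R1", "R2a", "R2b1", "R2b2", "R3", "RESP", "OX", "FERM", "ACPROD",
    "SUCCPROD", "EX_co2", "EX_etoh", "EX_ac", "EX_succ", "BIOMASS",
)


@dataclass
class SyntheticSpec:
    """Study design and generator knobs for one synthetic dataset.

    Defaults mirror the chemostat design the package targets: 29 samples =
    5 wild-type dilution levels + 24 knockout samples, 79 transcript and 60
    protein features, glucose and oxygen uptake as the two measured inputs.
    Knockout samples draw their glucose level uniformly from the dilution
    range so the toy dataset spans enough distinct conditions to be
    learnable. Flux units are mmol gDW^-1 h^-1 throughout.
    """

    n_samples: int = 29
    glc_levels: tuple = (2.0, 4.0, 6.0, 8.0, 10.0)
    o2_max: float = 5.0  # below the top glucose levels: overflow secretion active
    ko_genes: tuple = ("g_R2a", "g_R2b1", "g_ACPROD", "g_FERM", "g_SUCC", "g_OX")
    n_transcripts: int = 79
    n_proteins: int = 60
    omics_noise_sd: float = 0.05
    target_noise_sd: float = 0.0
    link: str = "saturating"  # or "linear"
    overflow_frac: float = 0.0  # glucose fraction forced into fermentation
    offspace_delta: float = 0.0
    reference_ids: list | None = None  # None -> every split reaction
    include_dead_end: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.omics_noise_sd < 0 or self.target_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.offspace_delta < 0:
            raise ValueError("offspace_delta must be >= 0")
        if self.n_samples < 1:
            raise ValueError("need at least one sample")


@dataclass
class OmicsDataset:
    """Samples x (transcripts + proteins + measured inputs) with references.

    ``features`` holds every model input; the measured input exchange fluxes
    live in columns ``input_cols`` (named ``uptake[<reaction>]`` so feature
    and reference-flux label sets stay disjoint) and correspond, in order,
    to the directional reactions ``input_reaction_ids`` of the split model.
    """

    features: pd.DataFrame
    reference_fluxes: pd.DataFrame
    input_cols: list[str]
    input_reaction_ids: list[str]
    transcript_cols: list[str] = field(default_factory=list)
    protein_cols: list[str] = field(default_factory=list)
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.features.isna().any().any() or self.reference_fluxes.isna().any().any():
            raise ValueError("dataset contains missing values")
        if not self.features.index.equals(self.reference_fluxes.index):
            raise ValueError("feature and reference tables disagree on samples")
        overlap = set(self.features.columns) & set(self.reference_fluxes.columns)
        if overlap:
            raise ValueError(f"feature/target label collision: {sorted(overlap)}")
        missing = [c for c in self.input_cols if c not in self.features.columns]
        if missing:
            raise ValueError(f"input columns absent from features: {missing}")
        if len(self.input_cols) != len(self.input_reaction_ids):
            raise ValueError("input_cols and input_reaction_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.features.index)

    def vin(self) -> np.ndarray:
        return self.features[self.input_cols].to_numpy(dtype=float)

    def subset(self, sample_ids) -> "OmicsDataset":
        return OmicsDataset(
            features=self.features.loc[sample_ids].copy(),
            reference_fluxes=self.reference_fluxes.loc[sample_ids].copy(),
            input_cols=list(self.input_cols),
            input_reaction_ids=list(self.input_reaction_ids),
            transcript_cols=list(self.transcript_cols),
            protein_cols=list(self.protein_cols),
            metadata=self.metadata.loc[sample_ids].copy()
            if len(self.metadata)
            else self.metadata,
        )


def _input_col(rid: str) -> str:
    return f"uptake[{rid}]"


# ---------------------------------------------------------------------------
# toy model
# ---------------------------------------------------------------------------

def make_toy_gem(spec: SyntheticSpec | None = None) -> cobra.Model:
    """A small branched metabolic network with known behavior.

    Glucose is taken up and routed through a linear chain with one parallel
    two-step bypass and one reversible step; the end product is either
    respired (consuming oxygen, feeding biomass) or overflows into acetate
    (cheap, 1 step) or ethanol (dearer, double secretion flux) when oxygen
    is limiting. Biomass production is the objective. One dead-end reaction
    is included (removable by flux-variability reduction). The returned
    model is unsplit; pass it through :func:`split_reversible` before
    building a mechanistic context.
    """
    spec = spec or SyntheticSpec()
    model = cobra.Model("toy_overflow")
    model.compartments = {"c": "cytosol", "e": "extracellular"}
    mets = {
        mid: cobra.Metabolite(mid, compartment="e" if mid.endswith("_e") else "c")
        for mid in (
            "glc_e", "glc_c", "a", "b", "c", "d", "e",
            "o2_e", "o2_c", "co2_c", "co2_e",
            "etoh_c", "etoh_e", "ac_c", "ac_e",
            "succ_c", "succ_e", "x",
        )
    }

    def rxn(rid, stoich, lb, ub, gene=""):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        r.add_metabolites({mets[m]: c for m, c in stoich.items()})
        if gene:
            r.gene_reaction_rule = gene
        return r

    reactions = [
        rxn("EX_glc", {"glc_e": -1}, -10.0, 1000.0),
        rxn("GLCt", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0, "g_GLCt"),
        rxn("EX_o2", {"o2_e": -1}, -20.0, 1000.0),
        rxn("O2t", {"o2_e": -1, "o2_c": 1}, 0.0, 1000.0, "g_O2t"),
        rxn("R1", {"glc_c": -1, "a": 1}, 0.0, 1000.0, "g_R1"),
        rxn("R2a", {"a": -1, "b": 1}, 0.0, 1000.0, "g_R2a"),
        rxn("R2b1", {"a": -1, "c": 1}, 0.0, 1000.0, "g_R2b1"),
        rxn("R2b2", {"c": -1, "b": 1}, 0.0, 1000.0, "g_R2b2"),
        rxn("R3", {"b": -1, "d": 1}, -1000.0, 1000.0, "g_R3"),
        rxn("RESP", {"d": -1, "o2_c": -1, "e": 1, "co2_c": 1}, 0.0, 1000.0, "g_RESP"),
        rxn("OX", {"d": -1, "o2_c": -2, "co2_c": 3}, 0.0, 1000.0, "g_OX"),
        rxn("ACPROD", {"d": -1, "ac_c": 1}, 0.0, 1000.0, "g_ACPROD"),
        rxn("FERM", {"d": -1, "etoh_c": 2, "co2_c": 1}, 0.0, 1000.0, "g_FERM"),
        rxn("SUCCPROD", {"d": -1, "succ_c": 2}, 0.0, 1000.0, "g_SUCC"),
        rxn("SUCCt", {"succ_c": -1, "succ_e": 1}, 0.0, 1000.0),
        rxn("EX_succ", {"succ_e": -1}, 0.0, 1000.0),
        rxn("CO2t", {"co2_c": -1, "co2_e": 1}, 0.0, 1000.0),
        rxn("EX_co2", {"co2_e": -1}, 0.0, 1000.0),
        rxn("ETOHt", {"etoh_c": -1, "etoh_e": 1}, 0.0, 1000.0),
        rxn("EX_etoh", {"etoh_e": -1}, 0.0, 1000.0),
        rxn("ACt", {"ac_c": -1, "ac_e": 1}, 0.0, 1000.0),
        rxn("EX_ac", {"ac_e": -1}, 0.0, 1000.0),
        rxn("BIOMASS", {"e": -1}, 0.0, 1000.0),
    ]
    if spec.include_dead_end:
        reactions.append(rxn("DEAD", {"a": -1, "x": 1}, 0.0, 1000.0, "g_DEAD"))
    model.add_reactions(reactions)
    model.objective = "BIOMASS"
    if np.isnan(model.slim_optimize()) or model.slim_optimize() <= 0:
        raise RuntimeError("toy model construction is infeasible")
    return model


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------

def _conditions(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i, level in enumerate(spec.glc_levels[: spec.n_samples]):
        rows.append({"sample": f"WT_D{i}", "strain": "WT", "ko_gene": "", "glc": level})
    lo, hi = min(spec.glc_levels), max(spec.glc_levels)
    i = 0
    while len(rows) < spec.n_samples:
        gene = spec.ko_genes[i % len(spec.ko_genes)]
        rows.append(
            {
                "sample": f"KO_{gene}_{i}",
                "strain": f"d{gene}",
                "ko_gene": gene,
                "glc": float(rng.uniform(lo, hi)),
            }
        )
        i += 1
    return pd.DataFrame(rows).set_index("sample")


def _omics_map(spec: SyntheticSpec, internal: list[str], rng: np.random.Generator):
    """Assign each omics feature a flux subset, weights and link parameters."""
    features = []
    names = [f"tx_{i:03d}" for i in range(spec.n_transcripts)] + [
        f"prot_{i:03d}" for i in range(spec.n_proteins)
    ]
    for name in names:
        k = int(rng.integers(1, 4))
        rids = list(rng.choice(internal, size=k, replace=False))
        features.append(
            {
                "name": name,
                "rids": rids,
                "w": rng.uniform(0.5, 1.5, size=k),
                "K": float(rng.uniform(1.0, 10.0)),
                "gain": float(rng.uniform(0.5, 2.0)),
            }
        )
    return features


def simulate_dataset(model: cobra.Model, spec: SyntheticSpec) -> OmicsDataset:
    """Simulate an omics dataset with pFBA ground truth on a split toy model.

    Per sample: the condition fixes glucose uptake (both bounds) and caps
    oxygen uptake, applies the sample's gene knockout, and parsimonious FBA
    gives the true flux vector. Transcript/protein features are noisy link
    functions of flux subsets; the two measured inputs are copied from the
    true solution. Reference targets are the (optionally noise- and
    off-space-perturbed) true fluxes projected onto the reference panel.
    Infeasible or growthless conditions are skipped with a log entry. All
    randomness flows from ``spec.seed``.
    """
    if any(r.lower_bound < 0 for r in model.reactions):
        raise ValueError("simulate_dataset expects a split model")
    rng = np.random.default_rng(spec.seed)
    conditions = _conditions(spec, rng)
    rids = [r.id for r in model.reactions]
    internal = [
        r.id
        for r in model.reactions
        if not r.id.startswith("EX_") and r.id != "BIOMASS"
    ]
    omics = _omics_map(spec, internal, rng)
    S = stoichiometric_matrix(model)

    ref_ids = spec.reference_ids
    if ref_ids is None:
        ref_ids = rids
        proj = build_projection(model, [(rid, {rid: 1.0}) for rid in rids])
    else:
        proj = build_projection(model, net_flux_targets(model, ref_ids))
    Pref = proj.matrix

    truth, feats, meta_rows, ids = [], [], [], []
    for sample, cond in conditions.iterrows():
        overrides = {
            GLC_UPTAKE: (cond["glc"], cond["glc"]),
            "EX_glc_fwd": (0.0, 0.0),
            O2_UPTAKE: (0.0, spec.o2_max),
        }
        # regulatory overflow: part of the feed ferments even when oxygen
        # would allow full respiration — behavior parsimonious FBA cannot
        # predict from the uptakes alone
        if spec.overflow_frac > 0 and cond["ko_gene"] != "g_FERM":
            overrides["FERM"] = (spec.overflow_frac * cond["glc"] / 2.0, 1000.0)
        with model:
            if cond["ko_gene"] and cond["ko_gene"] in model.genes:
                model.genes.get_by_id(cond["ko_gene"]).knock_out()
            sol = solve_pfba(model, overrides)
        if sol.status != "optimal" or (sol.objective_value or 0.0) <= 1e-9:
            logger.info("skipping infeasible/growthless condition %s", sample)
            continue
        v = sol.fluxes.reindex(rids).to_numpy(dtype=float)
        truth.append(v)
        ids.append(sample)
        meta_rows.append(cond)

    if not truth:
        raise RuntimeError("no feasible condition in the grid")
    V = np.vstack(truth)
    flux_by_id = pd.DataFrame(V, index=ids, columns=rids)

    # omics features: link(weighted flux subset) + Gaussian noise
    for feat in omics:
        s = flux_by_id[feat["rids"]].abs().to_numpy() @ feat["w"]
        if spec.link == "saturating":
            base = feat["gain"] * s / (s + feat["K"])
        elif spec.link == "linear":
            base = feat["gain"] * s
        else:
            raise ValueError(f"unknown link {spec.link!r}")
        feats.append(base + rng.normal(0.0, spec.omics_noise_sd, size=len(ids)))
    feat_names = [f["name"] for f in omics]
    features = pd.DataFrame(np.column_stack(feats) if feats else np.empty((len(ids), 0)),
                            index=ids, columns=feat_names)

    # measured inputs, copied from the true solution
    input_rids = [GLC_UPTAKE, O2_UPTAKE]
    input_cols = [_input_col(r) for r in input_rids]
    for col, rid in zip(input_cols, input_rids):
        features[col] = flux_by_id[rid]

    # reference targets, optionally pushed off the solution space
    V_t = V.copy()
    if spec.offspace_delta > 0:
        for i in range(V_t.shape[0]):
            y = rng.normal(size=S.shape[0])
            u = S.T @ y
            u /= np.linalg.norm(u)
            V_t[i] += spec.offspace_delta * u
    targets = V_t @ Pref.T
    if spec.target_noise_sd > 0:
        targets = targets + rng.normal(0.0, spec.target_noise_sd, size=targets.shape)
    reference = pd.DataFrame(targets, index=ids, columns=list(ref_ids))

    tx_cols = [f["name"] for f in omics if f["name"].startswith("tx_")]
    prot_cols = [f["name"] for f in omics if f["name"].startswith("prot_")]
    return OmicsDataset(
        features=features,
        reference_fluxes=reference,
        input_cols=input_cols,
        input_reaction_ids=input_rids,
        transcript_cols=tx_cols,
        protein_cols=prot_cols,
        metadata=pd.DataFrame(meta_rows, index=ids),
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def write_omics_tables(dataset: OmicsDataset, outdir: str) -> dict:
    """Write the dataset as transcripts/proteins/fluxes (+metadata) CSVs.

    The flux table holds the measured input exchanges (columns named by
    their directional reaction ids) alongside the reference-flux columns.
    Returns the mapping of table name to file path.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": out / "transcripts.csv",
        "proteins": out / "proteins.csv",
        "fluxes": out / "fluxes.csv",
        "metadata": out / "metadata.csv",
    }
    dataset.features[dataset.transcript_cols].to_csv(paths["transcripts"])
    dataset.features[dataset.protein_cols].to_csv(paths["proteins"])
    fluxes = pd.DataFrame(index=dataset.features.index)
    for col, rid in zip(dataset.input_cols, dataset.input_reaction_ids):
        fluxes[rid] = dataset.features[col]
    overlap = set(dataset.input_reaction_ids) & set(dataset.reference_fluxes.columns)
    if overlap:
        raise ValueError(
            "cannot serialize: input exchanges also appear as reference targets "
            f"({sorted(overlap)}); use a disjoint reference panel"
        )
    fluxes = fluxes.join(dataset.reference_fluxes)
    fluxes.to_csv(paths["fluxes"])
    dataset.metadata.to_csv(paths["metadata"])
    return {k: str(v) for k, v in paths.items()}


def read_omics_tables(
    transcripts_path: str,
    proteins_path: str,
    fluxes_path: str,
    input_ids: list[str],
    metadata_path: str | None = None,
) -> OmicsDataset:
    """Join the three measurement tables on sample id into a dataset.

    ``input_ids`` names the flux-table columns carrying the measured input
    exchanges (directional reaction ids of the split model); every other
    flux column is a reference target. Sample-id mismatches or missing cells
    raise with the offending ids/cells listed.
    """
    tx = pd.read_csv(transcripts_path, index_col=0)
    prot = pd.read_csv(proteins_path, index_col=0)
    flux = pd.read_csv(fluxes_path, index_col=0)

    sets = {"transcripts": set(tx.index), "proteins": set(prot.index),
            "fluxes": set(flux.index)}
    common = set.intersection(*sets.values())
    bad = {name: sorted(ids - common) for name, ids in sets.items() if ids - common}
    if bad:
        raise ValueError(f"sample ids not shared by all tables: {bad}")
    order = [s for s in tx.index if s in common]
    tx, prot, flux = tx.loc[order], prot.loc[order], flux.loc[order]

    for name, df in (("transcripts", tx), ("proteins", prot), ("fluxes", flux)):
        if df.isna().any().any():
            cells = [
                (str(i), str(c))
                for i, c in zip(*np.where(df.isna().to_numpy()))
            ]
            raise ValueError(f"missing cells in {name} table: {cells[:10]}")

    missing = [rid for rid in input_ids if rid not in flux.columns]
    if missing:
        raise ValueError(f"flux table lacks declared input columns: {missing}")
    features = tx.join(prot)
    input_cols = [_input_col(rid) for rid in input_ids]
    for col, rid in zip(input_cols, input_ids):
        features[col] = flux[rid]
    reference = flux.drop(columns=list(input_ids))
    return OmicsDataset(
        features=features,
        reference_fluxes=reference,
        input_cols=input_cols,
        input_reaction_ids=list(input_ids),
        transcript_cols=list(tx.columns),
        protein_cols=list(prot.columns),
        metadata=pd.read_csv(metadata_path, index_col=0).loc[order]
        if metadata_path
        else pd.DataFrame(index=features.index),
    )
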