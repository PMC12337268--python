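"""Synthetic dual-transcriptome datasets with planted, recorded ground truth.

The generator emulates the study design this pipeline targets: 20 rhizobial
strains x 4 nodule RNA-seq replicates, ~6,000 symbiont genes on a multipartite
genome (chromosome, pSymA, pSymB, plus a small accessory plasmid carried by 8
strains), ~5,000 host genes, replicon-specific core/shell/cloud frequency
profiles, planted intermediate-frequency syntenic gene clusters with biomass
effects, planted coexpression modules in both organisms, and a strain-level
shoot-biomass phenotype with coefficient of variation ~0.6.

A single latent "partner quality" axis ``Q`` per strain ties the planted
structure together: trait-linked clusters are carried by the strains at one
end of ``Q``, trait-coupled modules have strain factors correlated with ``Q``,
and biomass loads on clusters and module factors plus residual noise.  This
mirrors the empirical picture in which cluster presence, module eigengenes,
and plant biomass covary along one quality gradient, and it lets strong
gene-trait, module-trait, and cross-kingdom signals coexist within a unit
variance budget.

All randomness flows from a single seed; identical parameters + seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pavcoex import io as pio

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class RepliconProfile:
    """Target gene-frequency mixture for one replicon.

    ``core``, ``shell``, ``cloud`` are the expected fractions of gene groups
    in each frequency class; core genes are fixed in all strains, shell
    frequencies are Uniform(0.15, 0.95), cloud Uniform(1/n_strains, 0.15).
    """

    n_genes: int
    core: float
    shell: float
    cloud: float

    def __post_init__(self):
        total = self.core + self.shell + self.cloud
        if not np.isclose(total, 1.0):
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if min(self.core, self.shell, self.cloud) < 0:
            raise ValueError("class fractions must be non-negative")


@dataclass(frozen=True)
class PlantedCluster:
    """A run of adjacent genes sharing one presence pattern and a trait effect.

    ``effect`` is the approximate standardized biomass difference (in units of
    the total among-strain biomass SD) between carrier and non-carrier
    strains; its sign decides whether the high- or low-quality strains carry
    the cluster.  ``frequency`` is the carrier fraction.
    """

    name: str
    size: int
    replicon: str
    frequency: float
    effect: float

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("planted clusters need >= 2 genes")
        if not 0 < self.frequency < 1:
            raise ValueError("cluster frequency must be in (0, 1)")


@dataclass(frozen=True)
class PlantedModule:
    """A planted coexpression module.

    ``loading`` scales the (log-scale) effect of the module's strain factor on
    member-gene expression; ``trait_coupling`` is the module factor's weight in
    the biomass model (relative units, see :func:`simulate_phenotype`);
    ``quality_cor`` is the correlation of the module's strain factor with the
    latent quality axis Q.
    """

    name: str
    size: int
    loading: float = 0.3
    trait_coupling: float = 0.0
    quality_cor: float = 0.0

    def __post_init__(self):
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not -1 <= self.quality_cor <= 1:
            raise ValueError("quality_cor must be in [-1, 1]")


def _default_replicons() -> dict:
    # Core fractions follow the study's per-replicon pangenome summary
    # (pSymA 19.9%, chromosome 56.1%, pSymB 67.9%); the shell/cloud split of
    # the remainder is a generator choice.
    return {
        "chromosome": RepliconProfile(3300, 0.561, 0.329, 0.110),
        "pSymA": RepliconProfile(1300, 0.199, 0.601, 0.200),
        "pSymB": RepliconProfile(1400, 0.679, 0.241, 0.080),
    }


def _default_clusters() -> tuple:
    # Two trait-linked clusters at intermediate frequency with opposite
    # effects (a C2-like high-quality cluster and a C3-like low-quality one)
    # plus two neutral clusters, all on the symbiotic megaplasmid.
    return (
        PlantedCluster("plusA", 4, "pSymA", 0.5, +1.2),
        PlantedCluster("minusA", 10, "pSymA", 0.5, -1.2),
        PlantedCluster("neutralA", 3, "pSymA", 0.35, 0.0),
        PlantedCluster("neutralB", 5, "pSymA", 0.65, 0.0),
    )


def _default_symbiont_modules() -> tuple:
    return (
        PlantedModule("s1", 600),
        PlantedModule("s2", 400, trait_coupling=0.6, quality_cor=0.95),
        PlantedModule("s3", 250),
        PlantedModule("s4", 150),
        PlantedModule("s5", 100),
        PlantedModule("s6", 60),
    )


def _default_host_modules() -> tuple:
    return (
        PlantedModule("h1", 800, trait_coupling=0.4, quality_cor=0.95),
        PlantedModule("h2", 500),
        PlantedModule("h3", 300),
        PlantedModule("h4", 200),
        PlantedModule("h5", 120),
    )


@dataclass(frozen=True)
class SimParams:
    """All knobs of the generator; defaults emulate the study conditions."""

    n_strains: int = 20
    n_reps: int = 4
    replicons: Mapping[str, RepliconProfile] = field(default_factory=_default_replicons)
    accessory_name: str = "pAcc"
    accessory_genes: int = 60
    accessory_carriers: int = 8
    planted_clusters: Sequence[PlantedCluster] = field(default_factory=_default_clusters)
    symbiont_modules: Sequence[PlantedModule] = field(default_factory=_default_symbiont_modules)
    host_modules: Sequence[PlantedModule] = field(default_factory=_default_host_modules)
    n_host_genes: int = 5200
    nb_dispersion: float = 15.0
    lib_size_range: tuple = (2_000_000, 5_000_000)
    contamination_rate: float = 0.0  # delta: CPM observed for truly absent genes
    substitution_rate: float = 0.005
    revcomp_fraction: float = 0.3
    phenotype_cv_target: float = 0.60
    biomass_mean: float = 0.26  # g; sqrt(0.024)/0.60
    resid_frac: float = 0.15  # fraction of among-strain biomass variance from noise
    n_pheno_reps: int = 10
    within_strain_sd_frac: float = 0.5  # replicate noise, relative to among-strain SD
    # log2 baseline CPM ~ Normal(mean, sd); cluster members get a floor so
    # that planted clusters are clearly expressed when present
    log2_cpm_mean: float = 7.0
    log2_cpm_sd: float = 1.2
    cluster_min_cpm: float = 40.0
    gene_len_log_mean: float = np.log(900.0)
    gene_len_log_sd: float = 0.3
    intra_cluster_spacer: tuple = (50, 500)
    cluster_flank_spacer: tuple = (4000, 8000)
    background_spacer: tuple = (3050, 4500)  # flanking potential candidates
    tight_spacer: tuple = (50, 400)  # between genes that can never chain

    def __post_init__(self):
        if self.n_strains < 4:
            raise ValueError("need at least 4 strains")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if not 0 < self.accessory_carriers < self.n_strains:
            raise ValueError("accessory plasmid must be in a strict subset of strains")
        if self.contamination_rate < 0:
            raise ValueError("contamination_rate must be >= 0")
        if not 0 <= self.substitution_rate < 0.5:
            raise ValueError("substitution_rate must be in [0, 0.5)")
        for cl in self.planted_clusters:
            if cl.replicon not in self.replicons:
                raise ValueError(f"cluster {cl.name!r} on unknown replicon {cl.replicon!r}")
            if cl.size > self.replicons[cl.replicon].n_genes:
                raise ValueError(
                    f"cluster {cl.name!r} ({cl.size} genes) larger than replicon "
                    f"{cl.replicon!r} ({self.replicons[cl.replicon].n_genes} genes)"
                )
        if self.background_spacer[0] <= 3000:
            log.warning("background spacers <= 3000 bp can create spurious syntenic clusters")

    def strain_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimParams":
        """Build parameters from plain data (e.g. a YAML file)."""
        d = dict(d)
        if "replicons" in d:
            d["replicons"] = {name: RepliconProfile(**spec)
                              for name, spec in d["replicons"].items()}
        if "planted_clusters" in d:
            d["planted_clusters"] = tuple(
                PlantedCluster(**spec) for spec in d["planted_clusters"])
        for key in ("symbiont_modules", "host_modules"):
            if key in d:
                d[key] = tuple(PlantedModule(**spec) for spec in d[key])
        for key in ("lib_size_range", "intra_cluster_spacer", "cluster_flank_spacer",
                    "background_spacer", "tight_spacer"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# ground truth container

@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream evaluation."""

    presence: pd.DataFrame  # symbiont genes x strains, bool
    gene_class: pd.Series  # gene -> {core, shell, cloud}
    clusters: list  # dicts: name, replicon, genes, carriers, frequency, effect
    quality: pd.Series  # latent quality axis per strain
    factors: dict  # organism -> DataFrame (module x strain)
    module_membership: dict  # organism -> Series gene -> module name ('' = none)
    module_params: dict  # organism -> {module name: PlantedModule}
    gene_baseline_cpm: dict  # organism -> Series
    gene_loading: dict  # organism -> Series
    phenotype_decomposition: pd.DataFrame | None = None

    def check_consistency(self) -> None:
        """Assert internal agreement between the planted layers."""
        for cl in self.clusters:
            pat = self.presence.loc[cl["genes"]]
            expected = pd.Series(
                [s in set(cl["carriers"]) for s in self.presence.columns],
                index=self.presence.columns,
            )
            if not (pat.nunique(axis=0) == 1).all() or not pat.iloc[0].equals(expected):
                raise AssertionError(f"cluster {cl['name']} presence inconsistent")
        core = self.gene_class == "core"
        if not self.presence.loc[core[core].index].all(axis=None):
            raise AssertionError("a core gene is absent somewhere")
        for org, membership in self.module_membership.items():
            mods = set(membership.unique()) - {""}
            if not mods <= set(self.factors[org].index):
                raise AssertionError(f"{org} module without factors")

    def to_json(self, path) -> None:
        payload = {
            "presence": {
                "genes": list(self.presence.index),
                "strains": list(self.presence.columns),
                "data": self.presence.to_numpy().astype(int).tolist(),
            },
            "gene_class": self.gene_class.to_dict(),
            "clusters": [
                {**cl, "genes": list(cl["genes"]), "carriers": list(cl["carriers"])}
                for cl in self.clusters
            ],
            "quality": self.quality.to_dict(),
            "factors": {k: v.to_dict() for k, v in self.factors.items()},
            "module_membership": {k: v.to_dict() for k, v in self.module_membership.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            p = json.load(fh)
        presence = pd.DataFrame(
            np.asarray(p["presence"]["data"], dtype=bool),
            index=p["presence"]["genes"], columns=p["presence"]["strains"],
        )
        return cls(
            presence=presence,
            gene_class=pd.Series(p["gene_class"]),
            clusters=p["clusters"],
            quality=pd.Series(p["quality"]),
            factors={k: pd.DataFrame(v) for k, v in p["factors"].items()},
            module_membership={k: pd.Series(v) for k, v in p["module_membership"].items()},
            module_params={},
            gene_baseline_cpm={},
            gene_loading={},
        )


# ---------------------------------------------------------------------------
# pangenome layout and presence

def simulate_pangenome(params: SimParams, seed: int | np.random.Generator = 0):
    """Draw the pangenome: layout, gene groups, presence matrix, ground truth.

    Returns ``(annotation, groups, presence, truth)`` where ``annotation`` is
    the reference gene table (all gene groups, 1-based inclusive coordinates),
    ``groups`` the long-format gene-group membership table, and ``presence``
    the boolean gene x strain matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strains = params.strain_ids()
    n = params.n_strains

    # latent partner-quality axis, standardized across strains
    q = rng.standard_normal(n)
    q = (q - q.mean()) / q.std(ddof=0)
    quality = pd.Series(q, index=strains)
    order_by_q = np.argsort(-q)  # best strain first

    ann_rows = []
    presence_rows = {}
    gene_class = {}
    clusters_truth = []

    for rep_name, profile in params.replicons.items():
        planted_here = [c for c in params.planted_clusters if c.replicon == rep_name]
        n_background = profile.n_genes - sum(c.size for c in planted_here)
        if n_background < 0:
            raise ValueError(f"planted clusters exceed replicon {rep_name!r} size")

        # gene "slots" along the replicon: background singletons, with each
        # planted cluster occupying a contiguous run at a random slot
        slots: list = ["bg"] * n_background
        for cl in planted_here:
            pos = int(rng.integers(0, len(slots) + 1))
            slots.insert(pos, cl)

        # class of each background gene: multinomial at the profile fractions
        classes = rng.choice(
            ["core", "shell", "cloud"], size=n_background,
            p=[profile.core, profile.shell, profile.cloud],
        )

        cursor = 1
        gi = 0
        bg_i = 0
        prev_separable = True  # previous feature can never chain across a tight gap
        cluster_open = {}  # cluster name -> list of gene ids
        for slot in slots:
            if slot == "bg":
                members = [("bg", classes[bg_i])]
                bg_i += 1
            else:
                members = [(slot, None)] * slot.size

            first_of_cluster = True
            for member, cls_label in members:
                if member == "bg":
                    # Only shell genes can ever enter the candidate set (core
                    # genes are never on/off, cloud genes fail the >= 3-strain
                    # filter), so only shell-adjacent gaps must exceed the
                    # chaining rule; elsewhere realistic tight spacing is fine.
                    separable = cls_label != "shell"
                    gap_lo, gap_hi = (
                        params.tight_spacer if (separable and prev_separable)
                        else params.background_spacer
                    )
                    prev_separable = separable
                elif first_of_cluster:
                    gap_lo, gap_hi = params.cluster_flank_spacer
                    first_of_cluster = False
                    prev_separable = False
                else:
                    gap_lo, gap_hi = params.intra_cluster_spacer
                cursor += int(rng.integers(gap_lo, gap_hi + 1))
                length = int(np.clip(rng.lognormal(
                    params.gene_len_log_mean, params.gene_len_log_sd), 120, None))
                gene_id = f"{rep_name}_g{gi:05d}"
                gi += 1
                strand = "+" if rng.random() < 0.5 else "-"
                ann_rows.append(("ref", gene_id, rep_name, cursor, cursor + length - 1, strand))
                cursor += length

                if member == "bg":
                    gene_class[gene_id] = cls_label
                    presence_rows[gene_id] = _draw_presence(cls_label, n, rng)
                else:
                    gene_class[gene_id] = "shell"
                    cluster_open.setdefault(member.name, []).append(gene_id)
            if slot != "bg":
                # leave a wide gap after the cluster too
                cursor += int(rng.integers(*params.cluster_flank_spacer))

        for cl in planted_here:
            genes = cluster_open[cl.name]
            k = max(1, round(cl.frequency * n))
            if cl.effect > 0:
                carrier_idx = order_by_q[:k]
            elif cl.effect < 0:
                carrier_idx = order_by_q[-k:]
            else:
                carrier_idx = rng.choice(n, size=k, replace=False)
            pattern = np.zeros(n, dtype=bool)
            pattern[np.asarray(carrier_idx)] = True
            for g in genes:
                presence_rows[g] = pattern.copy()
            clusters_truth.append({
                "name": cl.name,
                "replicon": cl.replicon,
                "genes": genes,
                "carriers": [strains[i] for i in np.flatnonzero(pattern)],
                "frequency": cl.frequency,
                "effect": cl.effect,
            })

    # accessory plasmid: one extra replicon, present in a strict strain subset
    if params.accessory_genes > 0:
        carrier_idx = rng.choice(n, size=params.accessory_carriers, replace=False)
        pattern = np.zeros(n, dtype=bool)
        pattern[carrier_idx] = True
        cursor = 1
        for gi in range(params.accessory_genes):
            cursor += int(rng.integers(*params.background_spacer))
            length = int(np.clip(rng.lognormal(
                params.gene_len_log_mean, params.gene_len_log_sd), 120, None))
            gene_id = f"{params.accessory_name}_g{gi:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            ann_rows.append(("ref", gene_id, params.accessory_name,
                             cursor, cursor + length - 1, strand))
            cursor += length
            gene_class[gene_id] = "shell"
            presence_rows[gene_id] = pattern.copy()

    annotation = pd.DataFrame(
        ann_rows, columns=["strain_id", "gene_id", "replicon_id", "start", "end", "strand"]
    )
    presence = pd.DataFrame.from_dict(presence_rows, orient="index", columns=strains)
    presence = presence.loc[annotation["gene_id"]]

    groups = presence.rename_axis("group_id").reset_index().melt(
        id_vars="group_id", var_name="strain_id", value_name="present"
    )
    groups = groups[groups["present"]].drop(columns="present")
    groups["gene_id"] = groups["group_id"] + "@" + groups["strain_id"]
    groups = groups[["group_id", "strain_id", "gene_id"]].reset_index(drop=True)

    truth = GroundTruth(
        presence=presence,
        gene_class=pd.Series(gene_class).loc[presence.index],
        clusters=clusters_truth,
        quality=quality,
        factors={},
        module_membership={},
        module_params={},
        gene_baseline_cpm={},
        gene_loading={},
    )
    return annotation, groups, presence, truth


def _draw_presence(cls_label: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Carrier pattern for one background gene given its frequency class."""
    if cls_label == "core":
        return np.ones(n, dtype=bool)
    if cls_label == "shell":
        f = rng.uniform(0.15, 0.95)
    else:  # cloud
        f = rng.uniform(1.0 / n, 0.15)
    k = max(1, round(f * n))
    pattern = np.zeros(n, dtype=bool)
    pattern[rng.choice(n, size=k, replace=False)] = True
    return pattern


# ---------------------------------------------------------------------------
# module factors and counts

def _plant_modules(genes: pd.Index, modules: Sequence[PlantedModule],
                   quality: pd.Series, rng: np.random.Generator,
                   eligible: pd.Index | None = None):
    """Assign genes to modules and draw strain factors correlated with Q."""
    n_mod_genes = sum(m.size for m in modules)
    pool = genes if eligible is None else eligible
    if n_mod_genes > len(pool):
        raise ValueError("more module genes than available genes")
    chosen = rng.choice(len(pool), size=n_mod_genes, replace=False)
    membership = pd.Series("", index=genes, dtype=object)
    start = 0
    for m in modules:
        membership.iloc[
            genes.get_indexer(pool[chosen[start:start + m.size]])
        ] = m.name
        start += m.size

    q = quality.to_numpy()
    rows = []
    for m in modules:
        eta = rng.standard_normal(len(q))
        f = m.quality_cor * q + np.sqrt(1 - m.quality_cor ** 2) * eta
        rows.append(f)
    factors = pd.DataFrame(rows, index=[m.name for m in modules], columns=quality.index)
    return membership, factors


def _nb_sample(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative binomial with mean ``mean`` and shape (size) ``dispersion``."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = dispersion / (dispersion + mean[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_counts(presence: pd.DataFrame, truth: GroundTruth, params: SimParams,
                    seed: int | np.random.Generator = 0):
    """Draw symbiont and host count matrices plus the shared sample sheet.

    count ~ NB(mean = lib * 1e-6 * mu_g * exp(loading_g * factor_{m(g),s}),
    shape = nb_dispersion); genes absent in a strain have mean
    delta * lib * 1e-6 (default delta = 0, i.e. hard zeros).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strains = list(presence.columns)
    n = len(strains)
    samples = [f"{s}_r{r + 1}" for s in strains for r in range(params.n_reps)]
    sheet = pd.DataFrame({
        "sample_id": samples,
        "strain_id": [s for s in strains for _ in range(params.n_reps)],
        "replicate": [r + 1 for _ in strains for r in range(params.n_reps)],
    })

    cluster_genes = pd.Index(
        [g for cl in truth.clusters for g in cl["genes"]]
    )

    # --- symbiont ---
    # Planted modules live on genes present in every strain: they model
    # regulatory programs over the common genome, whereas accessory genes'
    # expression variation is dominated by their own presence/absence (the
    # signal the PAV branch models).
    sym_genes = presence.index
    always_present = presence.index[presence.all(axis=1)]
    membership, factors = _plant_modules(
        sym_genes, params.symbiont_modules, truth.quality, rng,
        eligible=always_present.difference(cluster_genes),
    )
    truth.module_membership["symbiont"] = membership
    truth.factors["symbiont"] = factors
    truth.module_params["symbiont"] = {m.name: m for m in params.symbiont_modules}

    mu = np.exp2(rng.normal(params.log2_cpm_mean, params.log2_cpm_sd, len(sym_genes)))
    is_cluster = sym_genes.isin(cluster_genes)
    mu[is_cluster] = np.maximum(mu[is_cluster], params.cluster_min_cpm)
    loading = np.where(membership.to_numpy() != "",
                       rng.uniform(0.7, 1.3, len(sym_genes)), 0.0)
    mod_loading = {m.name: m.loading for m in params.symbiont_modules}
    loading *= np.array([mod_loading.get(m, 0.0) for m in membership])
    truth.gene_baseline_cpm["symbiont"] = pd.Series(mu, index=sym_genes)
    truth.gene_loading["symbiont"] = pd.Series(loading, index=sym_genes)

    libs_sym = rng.uniform(*params.lib_size_range, size=len(samples))
    sym_counts = _counts_for(
        mu, loading, membership, factors, presence.to_numpy(), sheet,
        libs_sym, params, rng,
    )
    sym = pio.CountsMatrix(sym_genes, pd.Index(samples), sym_counts)

    # --- host (all genes present) ---
    host_genes = pd.Index([f"Mt_g{i:05d}" for i in range(params.n_host_genes)])
    h_membership, h_factors = _plant_modules(
        host_genes, params.host_modules, truth.quality, rng
    )
    truth.module_membership["host"] = h_membership
    truth.factors["host"] = h_factors
    truth.module_params["host"] = {m.name: m for m in params.host_modules}

    h_mu = np.exp2(rng.normal(params.log2_cpm_mean, params.log2_cpm_sd, len(host_genes)))
    h_loading = np.where(h_membership.to_numpy() != "",
                         rng.uniform(0.7, 1.3, len(host_genes)), 0.0)
    h_mod_loading = {m.name: m.loading for m in params.host_modules}
    h_loading *= np.array([h_mod_loading.get(m, 0.0) for m in h_membership])
    truth.gene_baseline_cpm["host"] = pd.Series(h_mu, index=host_genes)
    truth.gene_loading["host"] = pd.Series(h_loading, index=host_genes)

    libs_host = rng.uniform(*params.lib_size_range, size=len(samples))
    host_presence = np.ones((len(host_genes), n), dtype=bool)
    host_counts = _counts_for(
        h_mu, h_loading, h_membership, h_factors, host_presence, sheet,
        libs_host, params, rng,
    )
    host = pio.CountsMatrix(host_genes, pd.Index(samples), host_counts)

    return sym, host, sheet


def _counts_for(mu, loading, membership, factors, presence, sheet, libs, params, rng):
    strain_pos = {s: i for i, s in enumerate(dict.fromkeys(sheet["strain_id"]))}
    n_genes = len(mu)
    # per-gene, per-strain expression multiplier from the module factor
    fac = np.zeros((n_genes, len(strain_pos)))
    mem = membership.to_numpy()
    for mname in factors.index:
        rows = mem == mname
        fac[rows] = factors.loc[mname].to_numpy()[None, :]
    strain_mean_cpm = mu[:, None] * np.exp(loading[:, None] * fac)
    mean_present = np.where(presence, strain_mean_cpm, 0.0)
    if params.contamination_rate > 0:
        mean_present = np.where(presence, strain_mean_cpm, params.contamination_rate)

    counts = np.empty((n_genes, len(sheet)), dtype=np.int64)
    for j, (sample, strain) in enumerate(zip(sheet["sample_id"], sheet["strain_id"])):
        s = strain_pos[strain]
        mean = mean_present[:, s] * (libs[j] * 1e-6)
        counts[:, j] = _nb_sample(mean, params.nb_dispersion, rng)
    return counts


# ---------------------------------------------------------------------------
# phenotype

def simulate_phenotype(truth: GroundTruth, params: SimParams,
                       seed: int | np.random.Generator = 0):
    """Strain-mean phenotype table plus replicate-level biomass.

    biomass_s = mu0 * (1 + cv * (sqrt(1 - v_eps) * U~_s + sqrt(v_eps) * eps_s))
    where U_s = sum_c effect_c * presence_cs + sum_m gamma_m * factor_ms is the
    planted linear predictor (empirically standardized across strains, so the
    realized coefficient of variation tracks ``phenotype_cv_target``) and
    eps ~ N(0, 1) is residual strain noise with variance fraction v_eps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strains = list(truth.presence.columns)
    n = len(strains)
    mu0 = params.biomass_mean
    sigma = params.phenotype_cv_target * mu0

    u = np.zeros(n)
    parts = {}
    for cl in truth.clusters:
        x = np.array([s in set(cl["carriers"]) for s in strains], dtype=float)
        contrib = (cl["effect"] / 2.0) * (2 * x - 1)
        u += contrib
        parts[f"cluster:{cl['name']}"] = contrib
    for org, factors in truth.factors.items():
        for mname, mod in truth.module_params.get(org, {}).items():
            if mod.trait_coupling != 0.0:
                contrib = mod.trait_coupling * factors.loc[mname].to_numpy()
                u += contrib
                parts[f"module:{org}:{mname}"] = contrib

    v = params.resid_frac
    if u.std(ddof=0) > 0:
        u_std = (u - u.mean()) / u.std(ddof=0)
    else:
        # no planted signal: residual noise carries the whole CV target
        u_std = u * 0.0
        v = 1.0
    eps = rng.standard_normal(n)
    biomass = mu0 + sigma * (np.sqrt(1 - v) * u_std + np.sqrt(v) * eps)
    floor = 0.05 * mu0
    if (biomass < floor).any():
        warnings.warn(f"{int((biomass < floor).sum())} strain biomass values "
                      f"clipped at the positive floor {floor:.3g}")
        biomass = np.maximum(biomass, floor)

    decomposition = pd.DataFrame(
        {**parts, "standardized_predictor": u_std, "residual": np.sqrt(v) * eps},
        index=strains,
    )
    truth.phenotype_decomposition = decomposition

    # correlated companion traits (unitless), echoing the trait network:
    # root biomass, chlorophyll, leaf number and height move with shoot
    # biomass; nodule number moves against it
    z = (biomass - biomass.mean()) / max(biomass.std(ddof=0), 1e-12)
    def companion(weight):
        return weight * z + np.sqrt(max(1 - weight ** 2, 0.0)) * rng.standard_normal(n)

    pheno = pd.DataFrame({
        "shoot_biomass": biomass,
        "root_biomass": companion(0.8),
        "chlorophyll": companion(0.6),
        "leaf_number": companion(0.5),
        "height": companion(0.5),
        "nodule_number": companion(-0.5),
    }, index=pd.Index(strains, name="strain_id"))

    within_sd = params.within_strain_sd_frac * sigma
    rep_rows = []
    for i, s in enumerate(strains):
        reps = biomass[i] + within_sd * rng.standard_normal(params.n_pheno_reps)
        reps = np.maximum(reps, floor)
        for r, val in enumerate(reps, start=1):
            rep_rows.append((s, r, val))
    replicate_biomass = pd.DataFrame(
        rep_rows, columns=["strain_id", "replicate", "shoot_biomass"]
    )
    return pheno, replicate_biomass


# ---------------------------------------------------------------------------
# assemblies

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    k = rng.binomial(len(arr), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(arr), size=k, replace=False)
    # substitute with a different base
    shift = rng.integers(1, 4, size=k)
    base_idx = np.searchsorted(_BASES, arr[pos])  # A<C<G<T is sorted
    arr[pos] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode()


def simulate_assemblies(presence: pd.DataFrame, annotation: pd.DataFrame,
                        params: SimParams, seed: int | np.random.Generator = 0):
    """Reference gene sequences plus per-strain genome sequences.

    Each strain's replicon concatenates the reference spacers with the genes
    truly present in that strain, each copy mutated at ``substitution_rate``
    per site; a ``revcomp_fraction`` of gene placements is reverse
    complemented.  Absent genes leave no copy.

    Returns ``(gene_seqs, genomes)`` with ``genomes[strain][replicon] -> str``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ann = annotation.sort_values(["replicon_id", "start"])
    gene_seqs = {}
    for row in ann.itertuples(index=False):
        gene_seqs[row.gene_id] = _random_seq(rng, row.end - row.start + 1)

    # reference spacers between consecutive features (and leading spacer)
    spacers: dict[str, list[str]] = {}
    gene_order: dict[str, list] = {}
    for rep, sub in ann.groupby("replicon_id", sort=True):
        prev_end = 0
        sp = []
        order = []
        for row in sub.itertuples(index=False):
            sp.append(_random_seq(rng, row.start - prev_end - 1))
            order.append(row.gene_id)
            prev_end = row.end
        spacers[rep] = sp
        gene_order[rep] = order

    genomes: dict[str, dict[str, str]] = {}
    for strain in presence.columns:
        present = presence[strain]
        strain_genome = {}
        for rep in gene_order:
            pieces = []
            for sp, gid in zip(spacers[rep], gene_order[rep]):
                pieces.append(sp)
                if present.get(gid, False):
                    seq = _mutate(gene_seqs[gid], params.substitution_rate, rng)
                    if rng.random() < params.revcomp_fraction:
                        seq = revcomp(seq)
                    pieces.append(seq)
            seq = "".join(pieces)
            if seq:  # replicon absent entirely -> drop record
                strain_genome[rep] = seq
        genomes[strain] = strain_genome
    return gene_seqs, genomes


# ---------------------------------------------------------------------------
# one-call dataset

@dataclass
class Dataset:
    """A complete simulated study: inputs for every pipeline stage + truth."""

    params: SimParams
    seed: int
    annotation: pd.DataFrame
    groups: pd.DataFrame
    presence: pd.DataFrame
    symbiont_counts: pio.CountsMatrix
    host_counts: pio.CountsMatrix
    sample_sheet: pd.DataFrame
    phenotypes: pd.DataFrame
    replicate_biomass: pd.DataFrame
    gene_seqs: dict
    genomes: dict
    truth: GroundTruth

    def write_to(self, out_dir) -> dict:
        """Emit exactly the file formats the readers consume, plus truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.symbiont_counts.to_frame().to_csv(
            out / "symbiont_counts.tsv", sep="\t", index_label="gene_id")
        self.host_counts.to_frame().to_csv(
            out / "host_counts.tsv", sep="\t", index_label="gene_id")
        self.sample_sheet.to_csv(out / "sample_sheet.csv", index=False)
        self.phenotypes.to_csv(out / "phenotypes.csv")
        self.replicate_biomass.to_csv(out / "replicate_biomass.csv", index=False)
        pio.write_annotation(self.annotation, out / "reference_annotation.gff3")
        self.groups.to_csv(out / "gene_groups.tsv", sep="\t", index=False)
        pio.write_presence_matrix(self.presence, out / "true_presence.tsv")
        pio.write_fasta(self.gene_seqs, out / "reference_genes.fasta")
        genome_dir = out / "assemblies"
        genome_dir.mkdir(exist_ok=True)
        for strain, reps in self.genomes.items():
            pio.write_fasta(reps, genome_dir / f"{strain}.fasta")
        self.truth.to_json(out / "ground_truth.json")
        return {"out_dir": str(out)}


def simulate_dataset(params: SimParams | None = None, seed: int = 0,
                     with_assemblies: bool = True) -> Dataset:
    """Generate the full study from one seed (deterministic)."""
    params = params or SimParams()
    rng = np.random.default_rng(seed)
    annotation, groups, presence, truth = simulate_pangenome(params, rng)
    sym, host, sheet = simulate_counts(presence, truth, params, rng)
    pheno, rep_biomass = simulate_phenotype(truth, params, rng)
    if with_assemblies:
        gene_seqs, genomes = simulate_assemblies(presence, annotation, params, rng)
    else:
        gene_seqs, genomes = {}, {}
    truth.check_consistency()
    return Dataset(
        params=params, seed=seed, annotation=annotation, groups=groups,
        presence=presence, symbiont_counts=sym, host_counts=host,
        sample_sheet=sheet, phenotypes=pheno, replicate_biomass=rep_biomass,
        gene_seqs=gene_seqs, genomes=genomes, truth=truth,
    )
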