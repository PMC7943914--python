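"""Synthetic multi-patient, multi-condition scRNA-seq cohorts with planted ground truth.

The generator emulates a lung-cancer-style cohort spanning an ordered set of tissue
conditions (by default ``normal`` -> ``early`` -> ``advanced``): several patients per
condition, a handful of cell types with their own latent expression programs, malignant
cells carrying patient-specific copy-number segments, condition-specific differentially
expressed genes, condition-specific overdispersion, a named mitochondrial gene block, and
planted ligand-receptor co-expression. Counts are gamma-Poisson (negative binomial),
the standard noise model for droplet scRNA-seq.

Every planted effect is recorded in a :class:`GroundTruth` ledger so downstream
statistics can be scored against what was actually simulated.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

__all__ = [
    "CnvSegment",
    "LrPlant",
    "SimConfig",
    "GroundTruth",
    "default_config",
    "simulate_cohort",
    "write_fixture",
    "read_fixture",
]

DEFAULT_CONDITIONS = ("normal", "early", "advanced")
DEFAULT_CELL_TYPES = ("cancer", "epithelial", "T_cell", "B_cell", "myeloid", "fibroblast")
MALIGNANT_TYPE = "cancer"
MITO_PREFIX = "MT-"

# annotation TSV column order, fixed for interoperability
ANNOTATION_COLUMNS = ("barcode", "patient", "condition", "cell_type", "is_malignant")


@dataclass(frozen=True)
class CnvSegment:
    """A planted copy-number segment over a contiguous run of genome-ordered genes.

    ``start_index``/``end_index`` are half-open positions in the global genome order;
    ``log2_dosage`` is the log2 copy-dose (+1 = one extra copy relative to diploid in
    expression terms, -1 = heterozygous-like loss at half dose).
    """

    chrom: str
    start_index: int
    end_index: int
    log2_dosage: float


@dataclass(frozen=True)
class LrPlant:
    """A ligand-receptor pair planted (or deliberately not: a decoy) in the cohort.

    The ligand is expressed only in ``sender`` cells and the receptor only in
    ``receiver`` cells, and only within the listed ``conditions``. An empty condition
    tuple marks a decoy pair whose genes stay at near-zero baseline everywhere.
    """

    ligand: str
    receptor: str
    sender: str
    receiver: str
    conditions: tuple[str, ...]


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    ``type_program`` and ``condition_program`` map a label to ``(gene_indices,
    log2_effect)``: the listed genes have their mean shifted by ``2**log2_effect`` in
    cells carrying the label. ``dispersion`` is the per-condition NB inverse-size
    (variance = mu + dispersion * mu**2); 0 degenerates to Poisson.
    """

    n_patients_per_condition: int = 3
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_cells_per_patient: int = 500
    n_genes: int = 2000
    n_cell_types: int = len(DEFAULT_CELL_TYPES)
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    type_proportions: dict = field(default_factory=dict)  # condition -> {type: prob}
    base_expression: np.ndarray | None = None  # per-gene expected counts per typical cell
    type_program: dict = field(default_factory=dict)  # type -> (indices, log2 effect)
    condition_program: dict = field(default_factory=dict)  # condition -> (indices, log2 effect)
    dispersion: dict = field(default_factory=dict)  # condition -> NB inverse-size
    libsize_lognormal: tuple[float, float] = (0.0, 0.35)  # (mu, sigma) of log depth factor
    mito_gene_fraction: float = 0.005
    mito_expression_share: float = 0.06  # share of baseline expression carried by MT- genes
    cnv_segments: dict = field(default_factory=dict)  # patient -> [CnvSegment]
    lr_pairs: list = field(default_factory=list)  # [LrPlant]
    lr_expressed_mean: float = 1.0  # per-cell mean of a planted LR gene where active
    low_depth_cell_fraction: float = 0.02  # planted QC violations: shallow cells
    low_depth_scale: float = 0.03
    high_mito_cell_fraction: float = 0.02  # planted QC violations: dying cells
    high_mito_boost: float = 12.0
    seed: int = 0

    # -- derived helpers -------------------------------------------------------------
    @property
    def n_mito(self) -> int:
        return max(1, round(self.mito_gene_fraction * self.n_genes))

    @property
    def mito_indices(self) -> np.ndarray:
        # the mitochondrial block occupies the tail of the genome order
        return np.arange(self.n_genes - self.n_mito, self.n_genes)

    def gene_names(self) -> list[str]:
        n_reg = self.n_genes - self.n_mito
        names = [f"G{i + 1:04d}" for i in range(n_reg)]
        names += [f"{MITO_PREFIX}{i + 1}" for i in range(self.n_mito)]
        return names

    def patients(self) -> list[tuple[str, str]]:
        """(patient_id, condition) in deterministic cohort order."""
        out = []
        for cond in self.conditions:
            for i in range(self.n_patients_per_condition):
                out.append((f"{cond}_p{i + 1}", cond))
        return out

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_cells_per_patient < 0:
            raise SimConfigError("n_genes must be positive and n_cells_per_patient >= 0")
        if len(self.cell_types) != self.n_cell_types:
            raise SimConfigError("cell_types length does not match n_cell_types")
        if self.base_expression is None or len(self.base_expression) != self.n_genes:
            raise SimConfigError("base_expression must have length n_genes")
        if np.any(np.asarray(self.base_expression) < 0):
            raise SimConfigError("base_expression must be nonnegative")
        for cond in self.conditions:
            if cond not in self.dispersion:
                raise SimConfigError(f"missing dispersion for condition {cond!r}")
            if self.dispersion[cond] < 0:
                raise SimConfigError("dispersion must be >= 0")
            props = self.type_proportions.get(cond)
            if props is None or abs(sum(props.values()) - 1.0) > 1e-8:
                raise SimConfigError(f"type proportions for {cond!r} must sum to 1")
        mito = set(self.mito_indices.tolist())
        for label, (idx, _eff) in {**self.type_program, **self.condition_program}.items():
            if mito & set(idx):
                raise SimConfigError(f"program {label!r} overlaps the mitochondrial block")
            if max(idx, default=0) >= self.n_genes:
                raise SimConfigError(f"program {label!r} references genes beyond n_genes")
        for patient, segs in self.cnv_segments.items():
            for seg in segs:
                if not (0 <= seg.start_index < seg.end_index <= self.n_genes):
                    raise SimConfigError(f"CNV segment out of range for patient {patient!r}")
                if mito & set(range(seg.start_index, seg.end_index)):
                    raise SimConfigError("CNV segment overlaps the mitochondrial block")


@dataclass
class GroundTruth:
    """Ledger of every planted effect, keyed by gene/patient/cell identifiers."""

    conditions: list
    cell_types: list
    type_program: dict  # type -> {"genes": [...], "log2_effect": float}
    condition_program: dict  # condition -> {"genes": [...], "log2_effect": float}
    dispersion: dict
    cnv_segments: dict  # patient -> [{chrom, start_index, end_index, log2_dosage}]
    lr_pairs: list  # [{ligand, receptor, sender, receiver, conditions}]
    mito_genes: list
    qc_low_depth_cells: list
    qc_high_mito_cells: list
    n_genes: int
    seed: int

    def de_genes(self, condition: str) -> set:
        entry = self.condition_program.get(condition)
        return set(entry["genes"]) if entry else set()

    def marker_genes(self, cell_type: str) -> set:
        entry = self.type_program.get(cell_type)
        return set(entry["genes"]) if entry else set()

    def dosage_vector(self, patient: str) -> np.ndarray:
        """Per-gene log2 dosage applied to this patient's malignant cells."""
        dosage = np.zeros(self.n_genes)
        for seg in self.cnv_segments.get(patient, []):
            dosage[seg["start_index"]:seg["end_index"]] = seg["log2_dosage"]
        return dosage

    def planted_lr(self) -> list:
        return [p for p in self.lr_pairs if p["conditions"]]

    def decoy_lr(self) -> list:
        return [p for p in self.lr_pairs if not p["conditions"]]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _default_proportions(conditions, cell_types) -> dict:
    """Cell-type mixture per condition: no malignant cells in the first (normal-like)
    condition, a 30% malignant fraction in the others."""
    named = {
        "epithelial": 0.30, "T_cell": 0.25, "B_cell": 0.15,
        "myeloid": 0.20, "fibroblast": 0.10,
    }
    named_tumor = {
        "epithelial": 0.10, "T_cell": 0.22, "B_cell": 0.13,
        "myeloid": 0.15, "fibroblast": 0.10,
    }
    if len(cell_types) == 1:
        return {cond: {cell_types[0]: 1.0} for cond in conditions}
    props = {}
    for k, cond in enumerate(conditions):
        has_cancer = MALIGNANT_TYPE in cell_types and k > 0
        cancer_p = 0.30 if has_cancer else 0.0
        others = [t for t in cell_types if t != MALIGNANT_TYPE]
        table = named_tumor if has_cancer else named
        weights = np.array([table.get(t, 0.15) for t in others], dtype=float)
        weights = weights / weights.sum() * (1.0 - cancer_p)
        p = dict(zip(others, weights))
        if MALIGNANT_TYPE in cell_types:
            p[MALIGNANT_TYPE] = cancer_p
        props[cond] = p
    return props


def default_config(
    seed: int = 0,
    *,
    n_patients_per_condition: int = 3,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
    n_cells_per_patient: int = 500,
    n_genes: int = 2000,
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES,
    dispersion: dict | None = None,
    target_depth: float = 6000.0,
    n_type_markers: int = 50,
    type_log2_effect: float = 1.5,
    n_condition_de: int = 30,
    condition_log2_effect: float = 1.0,
    with_cnv: bool = True,
    with_lr: bool = True,
    n_chromosomes: int = 10,
    **overrides,
) -> SimConfig:
    """Build a fully explicit :class:`SimConfig` for the default study design.

    The defaults produce the bundled cohort: 3 conditions x 3 patients x 500 cells =
    4,500 cells over 2,000 genes on 10 chromosomes, dispersion 0.1 except 0.3 in the
    last (most advanced) condition, 50-gene cell-type programs at log2 effect 1.5,
    30-gene condition programs at log2 effect 1.0, three or four +/-1 / +/-0.58
    copy-number segments per malignant patient, and five planted plus three decoy
    ligand-receptor pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 90210]))
    cfg = SimConfig(
        n_patients_per_condition=n_patients_per_condition,
        conditions=tuple(conditions),
        n_cells_per_patient=n_cells_per_patient,
        n_genes=n_genes,
        n_cell_types=len(cell_types),
        cell_types=tuple(cell_types),
        seed=int(seed) % (2**31),
    )
    n_mito = cfg.n_mito
    mito_idx = cfg.mito_indices

    # baseline means: gamma-distributed with a fixed expression share in the MT- block
    base = rng.gamma(0.8, 1.0, n_genes)
    base = np.maximum(base, 1e-4)
    reg = np.setdiff1d(np.arange(n_genes), mito_idx)
    base[reg] *= (1.0 - cfg.mito_expression_share) * target_depth / base[reg].sum()
    base[mito_idx] = cfg.mito_expression_share * target_depth / n_mito

    # reserve near-silent genes for ligand-receptor planting
    n_lr_genes = 16
    lr_idx = rng.choice(reg, size=min(n_lr_genes, len(reg)), replace=False)
    base[lr_idx] = 0.002

    names = cfg.gene_names()
    eligible = np.setdiff1d(reg, lr_idx)
    # programs come from reasonably expressed genes so planted effects are detectable
    thr40, thr60 = np.quantile(base[eligible], [0.40, 0.60])
    pool_type = eligible[base[eligible] >= thr40]
    pool_type = rng.permutation(pool_type)
    type_program = {}
    used = 0
    for t in cfg.cell_types:
        k = min(n_type_markers, max(0, len(pool_type) - used))
        type_program[t] = (sorted(pool_type[used:used + k].tolist()), type_log2_effect)
        used += k
    taken = set(np.concatenate([v[0] for v in type_program.values()]).tolist()) if used else set()
    pool_cond = np.array([g for g in eligible if base[g] >= thr60 and g not in taken])
    pool_cond = rng.permutation(pool_cond)
    condition_program = {}
    used = 0
    for cond in cfg.conditions:
        k = min(n_condition_de, max(0, len(pool_cond) - used))
        condition_program[cond] = (sorted(pool_cond[used:used + k].tolist()), condition_log2_effect)
        used += k

    if dispersion is None:
        dispersion = {c: 0.1 for c in cfg.conditions}
        dispersion[cfg.conditions[-1]] = 0.3
    props = _default_proportions(cfg.conditions, cfg.cell_types)

    # CNV segments for malignant patients (all non-first conditions): one gain
    # shared by the whole cohort (recurrent arm-level events are a hallmark of
    # LUAD) plus patient-specific segments; the last chromosome hosts the MT-
    # block and is never used
    cnv_segments: dict = {}
    if with_cnv and MALIGNANT_TYPE in cfg.cell_types and n_chromosomes >= 3:
        chrom_size = n_genes // n_chromosomes
        margin = max(1, chrom_size // 8)
        length = min(150, max(5, chrom_size - 2 * margin))
        dosages = (1.0, -1.0, 0.58, -0.58)
        shared_chrom = n_chromosomes - 2
        shared = CnvSegment(f"chr{shared_chrom + 1}",
                            shared_chrom * chrom_size + margin,
                            shared_chrom * chrom_size + margin + length, 1.0)
        tumor_patients = [(p, c) for p, c in cfg.patients() if c != cfg.conditions[0]]
        for i, (patient, cond) in enumerate(tumor_patients):
            n_private = 2 if cfg.conditions.index(cond) == 1 else 3
            segs = [shared]
            for j in range(n_private):
                chrom_i = (2 * i + j) % (n_chromosomes - 2)
                start = chrom_i * chrom_size + margin
                segs.append(CnvSegment(f"chr{chrom_i + 1}", start, start + length,
                                       dosages[j % 4]))
            cnv_segments[patient] = segs

    lr_pairs: list[LrPlant] = []
    if with_lr and len(lr_idx) >= 16 and len(cfg.conditions) >= 3:
        L = [names[g] for g in lr_idx]
        c0, c1, c2 = cfg.conditions[0], cfg.conditions[1], cfg.conditions[2]
        lr_pairs = [
            LrPlant(L[0], L[1], "myeloid", "T_cell", (c2,)),          # unique, advanced
            LrPlant(L[2], L[3], "T_cell", "B_cell", (c1,)),           # unique, early
            LrPlant(L[4], L[5], "epithelial", "myeloid", (c0,)),      # unique, normal
            LrPlant(L[6], L[7], "myeloid", "fibroblast", (c0, c1, c2)),  # common, all
            LrPlant(L[8], L[9], MALIGNANT_TYPE, "myeloid", (c1, c2)),    # common, tumor-only
            LrPlant(L[10], L[11], "myeloid", "T_cell", ()),           # decoys: never active
            LrPlant(L[12], L[13], "T_cell", "myeloid", ()),
            LrPlant(L[14], L[15], "fibroblast", "B_cell", ()),
        ]
        lr_pairs = [p for p in lr_pairs
                    if p.sender in cfg.cell_types and p.receiver in cfg.cell_types]

    cfg.base_expression = base
    cfg.type_proportions = props
    cfg.type_program = type_program
    cfg.condition_program = condition_program
    cfg.dispersion = dict(dispersion)
    cfg.cnv_segments = cnv_segments
    cfg.lr_pairs = lr_pairs
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise SimConfigError(f"unknown SimConfig override {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def _gene_table(config: SimConfig, n_chromosomes: int = 10) -> pd.DataFrame:
    """BED-like gene table: chrom, start, end, gene, ordinal (global genome order)."""
    n = config.n_genes
    chrom_size = max(1, n // n_chromosomes)
    names = config.gene_names()
    chrom = [f"chr{min(i // chrom_size, n_chromosomes - 1) + 1}" for i in range(n)]
    start = np.arange(n, dtype=np.int64) * 1000
    df = pd.DataFrame({
        "chrom": chrom, "start": start, "end": start + 500,
        "gene": names, "ordinal": np.arange(n, dtype=np.int64),
    })
    return df


def simulate_cohort(config: SimConfig):
    """Draw a cohort from ``config``.

    Returns ``(adata, ground_truth)`` where ``adata.X`` holds raw NB counts (CSR,
    cells x genes), ``adata.obs`` the per-cell annotation (patient, condition,
    cell_type, is_malignant), and ``adata.var`` the genomic gene table. Identical
    config (including seed) gives identical output.
    """
    config.validate()
    base = np.asarray(config.base_expression, dtype=float)
    names = config.gene_names()
    name_to_idx = {g: i for i, g in enumerate(names)}
    mu_lib, sd_lib = config.libsize_lognormal

    # per-(condition, type) multiplicative weights shared by all patients
    log2_weight = {}
    for cond in config.conditions:
        cond_boost = np.zeros(config.n_genes)
        if cond in config.condition_program:
            idx, eff = config.condition_program[cond]
            cond_boost[np.asarray(idx, dtype=int)] += eff
        for t in config.cell_types:
            w = cond_boost.copy()
            if t in config.type_program:
                idx, eff = config.type_program[t]
                w[np.asarray(idx, dtype=int)] += eff
            log2_weight[(cond, t)] = w

    # planted ligand-receptor activity: gene mean forced to lr_expressed_mean in the
    # sender (ligand) / receiver (receptor) type within the planted conditions
    lr_boost: dict = {}
    for pair in config.lr_pairs:
        for cond in pair.conditions:
            for gene, ctype in ((pair.ligand, pair.sender), (pair.receptor, pair.receiver)):
                gi = name_to_idx[gene]
                lr_boost.setdefault((cond, ctype), []).append(gi)

    blocks, obs_rows = [], []
    low_depth_cells, high_mito_cells = [], []
    mito_idx = config.mito_indices
    for pi, (patient, cond) in enumerate(config.patients()):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, pi]))
        n = config.n_cells_per_patient
        props = config.type_proportions[cond]
        tnames = list(props.keys())
        tdraw = rng.choice(len(tnames), size=n, p=[props[t] for t in tnames])
        ctypes = np.array(tnames, dtype=object)[tdraw]
        depth = np.exp(rng.normal(mu_lib, sd_lib, n)) if sd_lib > 0 or mu_lib != 0 \
            else np.ones(n)

        n_low = round(config.low_depth_cell_fraction * n)
        n_high = round(config.high_mito_cell_fraction * n)
        perm = rng.permutation(n)
        low_i, high_i = perm[:n_low], perm[n_low:n_low + n_high]
        depth[low_i] *= config.low_depth_scale

        dosage = np.zeros(config.n_genes)
        for seg in config.cnv_segments.get(patient, []):
            dosage[seg.start_index:seg.end_index] = seg.log2_dosage

        phi = config.dispersion[cond]
        counts = np.empty((n, config.n_genes), dtype=np.int64)
        for t in sorted(set(ctypes.tolist())):  # fixed order: platform determinism
            mask = ctypes == t
            w = base * np.exp2(log2_weight[(cond, t)])
            if t == MALIGNANT_TYPE:
                w = w * np.exp2(dosage)
            boost_idx = lr_boost.get((cond, t))
            if boost_idx:
                w = w.copy()
                w[boost_idx] = config.lr_expressed_mean
            mu = depth[mask, None] * w[None, :]
            mito_rows = np.nonzero(np.isin(np.nonzero(mask)[0], high_i))[0]
            if mito_rows.size:
                mu[np.ix_(mito_rows, mito_idx)] *= config.high_mito_boost
            if phi > 1e-12:
                lam = rng.gamma(1.0 / phi, mu * phi)
            else:
                lam = mu
            counts[mask] = rng.poisson(lam)
        blocks.append(sparse.csr_matrix(counts))

        barcodes = [f"{patient}_c{i + 1:04d}" for i in range(n)]
        low_depth_cells += [barcodes[i] for i in sorted(low_i.tolist())]
        high_mito_cells += [barcodes[i] for i in sorted(high_i.tolist())]
        for i in range(n):
            obs_rows.append((barcodes[i], patient, cond, ctypes[i],
                             bool(ctypes[i] == MALIGNANT_TYPE)))

    if blocks:
        X = sparse.vstack(blocks, format="csr").astype(np.int64)
    else:
        X = sparse.csr_matrix((0, config.n_genes), dtype=np.int64)
    obs = pd.DataFrame(obs_rows, columns=list(ANNOTATION_COLUMNS))
    obs = obs.set_index("barcode")
    var = _gene_table(config).set_index("gene")
    adata = ad.AnnData(X=X, obs=obs, var=var)

    gt = GroundTruth(
        conditions=list(config.conditions),
        cell_types=list(config.cell_types),
        type_program={t: {"genes": [names[g] for g in idx], "log2_effect": eff}
                      for t, (idx, eff) in config.type_program.items() if idx},
        condition_program={c: {"genes": [names[g] for g in idx], "log2_effect": eff}
                           for c, (idx, eff) in config.condition_program.items() if idx},
        dispersion=dict(config.dispersion),
        cnv_segments={p: [asdict(s) for s in segs]
                      for p, segs in config.cnv_segments.items()},
        lr_pairs=[{**asdict(p), "conditions": list(p.conditions)} for p in config.lr_pairs],
        mito_genes=[names[g] for g in mito_idx],
        qc_low_depth_cells=low_depth_cells,
        qc_high_mito_cells=high_mito_cells,
        n_genes=config.n_genes,
        seed=config.seed,
    )
    return adata, gt


# ---------------------------------------------------------------------------------
# fixture I/O: MTX + 10x-style TSVs + annotation + BED-like gene table + truth JSON


def write_fixture(adata: ad.AnnData, ground_truth: GroundTruth | None, directory) -> dict:
    """Write a cohort as plain-text files; returns a {name: path} manifest.

    Layout follows the 10x convention (genes x cells MTX, headerless features/barcodes
    TSVs) plus an annotation TSV, a BED-like gene table, and the ground-truth JSON.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {}

    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    mtx = d / "matrix.mtx"
    mmwrite(str(mtx), X.T.tocoo(), field="integer")
    manifest["matrix"] = str(mtx)

    feats = d / "features.tsv"
    pd.DataFrame({
        "id": adata.var_names, "name": adata.var_names,
        "type": "Gene Expression",
    }).to_csv(feats, sep="\t", header=False, index=False)
    manifest["features"] = str(feats)

    bc = d / "barcodes.tsv"
    pd.Series(adata.obs_names).to_csv(bc, sep="\t", header=False, index=False)
    manifest["barcodes"] = str(bc)

    annot = d / "annotation.tsv"
    out = adata.obs.reset_index()
    out = out.rename(columns={out.columns[0]: "barcode"})
    out[list(ANNOTATION_COLUMNS)].to_csv(annot, sep="\t", index=False)
    manifest["annotation"] = str(annot)

    bed = d / "genes.bed"
    tab = adata.var.reset_index()
    tab = tab.rename(columns={tab.columns[0]: "gene"})
    tab[["chrom", "start", "end", "gene", "ordinal"]].to_csv(
        bed, sep="\t", header=False, index=False)
    manifest["genes"] = str(bed)

    gtp = d / "ground_truth.json"
    if ground_truth is not None:
        ground_truth.to_json(gtp)
    else:
        gtp.write_text("{}")
    manifest["ground_truth"] = str(gtp)
    return manifest


def read_fixture(directory):
    """Read a fixture written by :func:`write_fixture` back into memory.

    Returns ``(adata, ground_truth_or_None)``; the count matrix round-trips exactly.
    """
    d = Path(directory)
    M = mmread(str(d / "matrix.mtx"))
    X = sparse.csr_matrix(M.T).astype(np.int64)
    feats = pd.read_csv(d / "features.tsv", sep="\t", header=None,
                        names=["id", "name", "type"])
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str) \
        if (d / "barcodes.tsv").stat().st_size > 0 else pd.Series([], dtype=str)
    bed = pd.read_csv(d / "genes.bed", sep="\t", header=None,
                      names=["chrom", "start", "end", "gene", "ordinal"])
    var = bed.set_index("gene").loc[feats["id"].tolist()]
    annot = pd.read_csv(d / "annotation.tsv", sep="\t", dtype={"barcode": str})
    if len(annot):
        obs = annot.set_index("barcode").loc[barcodes.tolist()]
        obs["is_malignant"] = obs["is_malignant"].astype(bool)
    else:
        obs = pd.DataFrame(index=pd.Index(barcodes.tolist(), name="barcode"),
                           columns=["patient", "condition", "cell_type", "is_malignant"])
    adata = ad.AnnData(X=X, obs=obs, var=var)
    gt = None
    gtp = d / "ground_truth.json"
    if gtp.exists():
        payload = json.loads(gtp.read_text())
        if payload:
            gt = GroundTruth(**payload)
    return adata, gt
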