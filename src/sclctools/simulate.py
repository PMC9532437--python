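"""Synthetic scRNA-seq and bulk expression generator with ground truth.

Emulates the statistical structure the downstream stages assume for a
small-cell lung cancer (SCLC) cohort: per-patient malignant populations
carrying planted copy-number segments, transcription-factor-defined
subtype mixtures (ASCL1 / NEUROD1 / POU2F3 / YAP1), latent
proliferation / immune / hypoxia program activities, immune and stromal
compartments with marker blocks, batch log-shifts, planted
ligand-receptor pairs, negative-binomial UMI noise and log-normal
library sizes.  Every planted effect is recorded in :class:`SimTruth`
so recovery tests can score the pipeline against it.

The noise model: for cell j with library size L_j ~ LogNormal and gene
relative abundance p_i (softmax-normalized over genes, after all
multiplicative effects), counts are NB with mean L_j * p_i and fixed
dispersion (Gamma-Poisson mixture).  Program activity a in [0, 1]
multiplies its gene block's abundance by exp(a * effect); CNV dosage
multiplies segment genes in that patient's malignant cells only; TF
positivity is subject to Bernoulli detection dropout so that even
"positive" cells are occasionally negative, exercising thresholding
logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import BulkMatrix, CountMatrix, GeneAnnotation, GeneSetCollection

__all__ = ["SimConfig", "SimTruth", "generate_dataset", "generate_bulk"]

TF_GENES = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")
SUBTYPES = ("SCLC-A", "SCLC-N", "SCLC-A/N", "SCLC-P", "SCLC-Y", "non-NE")
#: which TFs are "on" for each subtype
SUBTYPE_TFS = {
    "SCLC-A": ("ASCL1",),
    "SCLC-N": ("NEUROD1",),
    "SCLC-A/N": ("ASCL1", "NEUROD1"),
    "SCLC-P": ("POU2F3",),
    "SCLC-Y": ("YAP1",),
    "non-NE": (),
}
COMPARTMENTS = ("malignant", "T", "myeloid", "B", "fibroblast", "normal_epithelial")


@dataclass
class SimConfig:
    """Configuration of the synthetic cohort.

    Defaults describe a small surgical cohort: a few patients, a few
    hundred cells each, ~2000 genes on 10 chromosomes, moderate UMI
    depth, subtype mixtures dominated by SCLC-A with an SCLC-A/N
    admixture, and one planted chromosomal loss and gain per patient.
    """

    n_genes: int = 2000
    n_chromosomes: int = 10
    n_patients: int = 3
    # cells per patient per compartment
    cells_per_compartment: dict = field(
        default_factory=lambda: {
            "malignant": 200,
            "T": 80,
            "myeloid": 60,
            "B": 30,
            "fibroblast": 30,
            "normal_epithelial": 60,
        }
    )
    nb_dispersion: float = 0.3  # Gamma shape = 1/dispersion
    libsize_meanlog: float = np.log(8000.0)
    libsize_sdlog: float = 0.3
    marker_block_size: int = 30
    marker_log_fc: float = 1.5  # natural-log fold elevation of markers
    # (patient index, chromosome index, start gene index on chrom, length, fold)
    cnv_segments: list = field(
        default_factory=lambda: [
            (0, 1, 20, 120, 0.5),
            (0, 4, 10, 120, 1.5),
            (1, 2, 30, 120, 0.5),
            (1, 6, 0, 150, 2.0),
            (2, 3, 40, 100, 1.5),
            (2, 8, 50, 120, 0.5),
        ]
    )
    subtype_fractions: dict = field(
        default_factory=lambda: {
            0: {"SCLC-A": 0.85, "non-NE": 0.15},
            1: {"SCLC-A": 0.45, "SCLC-A/N": 0.30, "SCLC-N": 0.10, "non-NE": 0.15},
            2: {"SCLC-P": 0.60, "non-NE": 0.40},
        }
    )
    tf_log_fc: float = 10.0  # elevation of an "on" TF over its (tiny) baseline
    tf_detection: float = 0.99  # Bernoulli detection of an "on" TF
    program_block_size: int = 45
    program_effect: float = 1.2  # abundance multiplier exp(activity * effect)
    program_beta: tuple = (1.2, 1.2)  # per-cell activity ~ Beta(a, b)
    n_decoy_sets: int = 5
    # planted ligand-receptor pairs: (source compartment, target compartment)
    lr_pairs: list = field(
        default_factory=lambda: [("malignant", "myeloid"), ("T", "malignant")]
    )
    lr_log_fc: float = 2.0
    n_batches: int = 2
    batch_shift_sd: float = 0.15  # sd of per-gene batch log-shift
    seed: int = 0

    def validate(self) -> None:
        for comp, n in self.cells_per_compartment.items():
            if comp not in COMPARTMENTS:
                raise ValueError(f"unknown compartment {comp!r}")
            if n < 0:
                raise ValueError("cell counts must be >= 0")
        genes_per_chrom = self.n_genes // self.n_chromosomes
        for pat, chrom, start, length, fold in self.cnv_segments:
            if not (0 <= pat < self.n_patients):
                raise ValueError(f"cnv segment patient {pat} out of range")
            if not (0 <= chrom < self.n_chromosomes):
                raise ValueError(f"cnv segment chromosome {chrom} out of range")
            if start < 0 or start + length > genes_per_chrom:
                raise ValueError(
                    f"cnv segment ({pat},{chrom},{start},{length}) exceeds its chromosome"
                )
        for pat, fracs in self.subtype_fractions.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"subtype fractions for patient {pat} sum to {total}")
            for name in fracs:
                if name not in SUBTYPES:
                    raise ValueError(f"unknown subtype {name!r}")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    cells: pd.DataFrame  # patient, compartment, malignant, subtype, activities, batch
    cnv_segments: list  # (patient id, chromosome name, start gene idx in chrom, length, fold)
    cnv_segment_genes: list  # gene-id list per segment, aligned with cnv_segments
    marker_genes: dict  # compartment -> list of marker gene ids
    program_genes: dict  # program name -> list of gene ids
    tf_genes: tuple
    lr_genes: list  # (ligand, receptor, source compartment, target compartment)


def _gene_names(cfg: SimConfig, rng: np.random.Generator):
    names = np.array([f"G{i:05d}" for i in range(cfg.n_genes)], dtype=object)
    genes_per_chrom = cfg.n_genes // cfg.n_chromosomes
    chroms = np.repeat(
        [str(c + 1) for c in range(cfg.n_chromosomes)], genes_per_chrom
    ).astype(object)
    # trailing genes (if n_genes not divisible) go on the last chromosome
    if len(chroms) < cfg.n_genes:
        chroms = np.concatenate(
            [chroms, np.full(cfg.n_genes - len(chroms), str(cfg.n_chromosomes), dtype=object)]
        )
    starts = np.concatenate(
        [
            np.sort(rng.choice(10_000_000, size=(chroms == str(c + 1)).sum(), replace=False))
            for c in range(cfg.n_chromosomes)
        ]
    )
    return names, chroms, starts


def generate_dataset(cfg: SimConfig):
    """Generate (CountMatrix, GeneAnnotation, GeneSetCollection, SimTruth).

    Deterministic for a fixed config (one RNG stream seeded from
    ``cfg.seed``): identical config + seed gives byte-identical counts.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    gene_names, chroms, starts = _gene_names(cfg, rng)
    genes_per_chrom = cfg.n_genes // cfg.n_chromosomes

    # --- reserve gene blocks -------------------------------------------------
    # layout: markers per compartment, then program blocks, then TFs, then LR
    cursor = 0
    marker_genes: dict = {}
    for comp in COMPARTMENTS:
        marker_genes[comp] = list(gene_names[cursor : cursor + cfg.marker_block_size])
        cursor += cfg.marker_block_size
    program_genes = {}
    for prog in ("proliferation", "immune", "hypoxia"):
        program_genes[prog] = list(gene_names[cursor : cursor + cfg.program_block_size])
        cursor += cfg.program_block_size
    tf_idx = np.arange(cursor, cursor + 4)
    for i, tf in enumerate(TF_GENES):
        gene_names[tf_idx[i]] = tf
    cursor += 4
    lr_genes = []
    for src, tgt in cfg.lr_pairs:
        lig, rec = gene_names[cursor], gene_names[cursor + 1]
        lr_genes.append((lig, rec, src, tgt))
        cursor += 2

    # --- cells ---------------------------------------------------------------
    records = []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1}"
        for comp in COMPARTMENTS:
            n = cfg.cells_per_compartment.get(comp, 0)
            if comp == "malignant":
                fracs = cfg.subtype_fractions.get(p, {"SCLC-A": 1.0})
                names = list(fracs)
                counts = np.floor(np.array([fracs[s] for s in names]) * n).astype(int)
                # distribute remainder deterministically to largest fractions
                rem = n - counts.sum()
                order = np.argsort([-fracs[s] for s in names], kind="stable")
                for k in range(rem):
                    counts[order[k % len(names)]] += 1
                subtypes = np.repeat(names, counts)
            else:
                subtypes = np.full(n, "", dtype=object)
            for j in range(n):
                records.append((pid, comp, comp == "malignant", subtypes[j]))
    cells = pd.DataFrame(records, columns=["patient", "compartment", "malignant", "subtype"])
    n_cells = len(cells)
    cells["cell_id"] = [f"C{i:05d}" for i in range(n_cells)]
    cells["batch"] = [f"B{i % cfg.n_batches + 1}" for i in range(n_cells)]
    for prog in program_genes:
        cells[f"activity_{prog}"] = 0.0

    # --- per-gene baseline abundance ----------------------------------------
    base_log = rng.normal(0.0, 1.0, size=cfg.n_genes)
    tf_mask = np.zeros(cfg.n_genes, dtype=bool)
    tf_mask[tf_idx] = True
    base_log[tf_mask] = -7.0  # TFs near-silent unless switched on

    batch_shift = rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_batches, cfg.n_genes))

    gene_lookup = {g: i for i, g in enumerate(gene_names)}
    marker_idx = {c: np.array([gene_lookup[g] for g in gs]) for c, gs in marker_genes.items()}
    program_idx = {p: np.array([gene_lookup[g] for g in gs]) for p, gs in program_genes.items()}
    tf_lookup = {tf: gene_lookup[tf] for tf in TF_GENES}

    # CNV dosage per (patient, gene)
    dosage = np.ones((cfg.n_patients, cfg.n_genes))
    truth_segments, truth_segment_genes = [], []
    for pat, chrom, start, length, fold in cfg.cnv_segments:
        g0 = chrom * genes_per_chrom + start
        dosage[pat, g0 : g0 + length] *= fold
        truth_segments.append((f"P{pat + 1}", str(chrom + 1), start, length, fold))
        truth_segment_genes.append(list(gene_names[g0 : g0 + length]))

    libsizes = rng.lognormal(cfg.libsize_meanlog, cfg.libsize_sdlog, size=n_cells)
    shape = 1.0 / cfg.nb_dispersion

    counts = np.zeros((cfg.n_genes, n_cells), dtype=np.int64)
    patients = cells["patient"].to_numpy()
    compartments = cells["compartment"].to_numpy()
    batches = cells["batch"].to_numpy()
    subtypes_col = cells["subtype"].to_numpy()
    activities = {p: rng.beta(*cfg.program_beta, size=n_cells) for p in program_genes}
    for prog, act in activities.items():
        cells[f"activity_{prog}"] = act

    for j in range(n_cells):
        log_mu = base_log.copy()
        log_mu += batch_shift[int(batches[j][1:]) - 1]
        comp = compartments[j]
        log_mu[marker_idx[comp]] += cfg.marker_log_fc
        if comp == "malignant":
            pat = int(patients[j][1:]) - 1
            log_mu += np.log(dosage[pat])
            for prog, idx in program_idx.items():
                log_mu[idx] += activities[prog][j] * cfg.program_effect
            for tf in SUBTYPE_TFS[subtypes_col[j]]:
                if rng.random() < cfg.tf_detection:
                    log_mu[tf_lookup[tf]] += cfg.tf_log_fc
        for lig, rec, src, tgt in lr_genes:
            if comp == src:
                log_mu[gene_lookup[lig]] += cfg.lr_log_fc
            if comp == tgt:
                log_mu[gene_lookup[rec]] += cfg.lr_log_fc
        p_gene = np.exp(log_mu - log_mu.max())
        p_gene /= p_gene.sum()
        mu = libsizes[j] * p_gene
        lam = rng.gamma(shape, mu / shape)
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=gene_names,
        cell_ids=cells["cell_id"].to_numpy(),
        cell_meta=cells.set_index("cell_id")[
            ["patient", "compartment", "subtype", "batch"]
        ].assign(
            tissue=np.where(compartments == "normal_epithelial", "NAT", "PT"),
            label=compartments,
        ),
    )
    ann = GeneAnnotation(
        pd.DataFrame({"gene_id": gene_names, "chromosome": chroms, "start": starts}),
        chromosomes=tuple(str(c + 1) for c in range(cfg.n_chromosomes)),
    )

    sets = {f"PROGRAM_{p.upper()}": list(gs) for p, gs in program_genes.items()}
    for d in range(cfg.n_decoy_sets):
        members = rng.choice(gene_names, size=cfg.program_block_size, replace=False)
        sets[f"DECOY_{d + 1}"] = list(members)
    collection = GeneSetCollection(sets=sets)

    truth = SimTruth(
        cells=cells.set_index("cell_id"),
        cnv_segments=truth_segments,
        cnv_segment_genes=truth_segment_genes,
        marker_genes=marker_genes,
        program_genes=program_genes,
        tf_genes=TF_GENES,
        lr_genes=lr_genes,
    )
    return cm, ann, collection, truth


def generate_bulk(
    n_samples: int = 50,
    n_genes: int = 500,
    n_signature: int = 45,
    hot_fraction: float = 0.5,
    effect_size: float = 2.0,
    seed: int = 0,
):
    """Generate a bulk gene x sample matrix with planted immune-hot samples.

    ``effect_size`` is the shift of signature-gene log-expression in hot
    samples, in units of the per-gene log-scale noise sd.  Returns
    ``(BulkMatrix, signature gene list, hot/cold label Series)``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 <= hot_fraction <= 1.0:
        raise ValueError("hot_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"BG{i:04d}" for i in range(n_genes)]
    signature = genes[:n_signature]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    n_hot = int(round(hot_fraction * n_samples))
    hot = np.zeros(n_samples, dtype=bool)
    hot[rng.choice(n_samples, size=n_hot, replace=False)] = True

    base = rng.normal(3.0, 1.0, size=(n_genes, 1))  # per-gene baseline log-expr
    noise_sd = 0.5
    log_expr = base + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    log_expr[:n_signature, hot] += effect_size * noise_sd
    values = pd.DataFrame(np.exp(log_expr), index=genes, columns=samples)
    labels = pd.Series(np.where(hot, "hot", "cold"), index=samples, name="label")
    bulk = BulkMatrix(values, sample_meta=labels.to_frame())
    return bulk, signature, labels
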