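"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure the analyses assume — skewed
clone-size distributions with rare dominant clones, epitope-specific CDR3 sets
sharing a planted sequence motif across subjects, cohorts differing in the
aggregate frequency of motif-bearing clones, pre/post sample pairs with
planted expansions and novel clones, and clustered single-cell expression with
specificity-linked cluster enrichment and ligand-receptor co-expression. Every
generator is a pure function of its configuration including the seed, and
every generated CDR3 passes the functional QC filter (C + interior + F over
the 20-letter alphabet, length >= 8).

Defaults: clone sizes lognormal(mu=0, sigma=2) (rare-dominant-clone
structure), sequencing depth 10^4 reads over 500 clones, CDR3 length 8-20,
uniform amino-acid composition, and central motif planting (antigen-contact
residues concentrate at the CDR3 loop apex).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .repertoire import AA_ALPHABET, Repertoire
from .sc import ExpressionMatrix
from .specificity import TrainingSet

__all__ = [
    "GeneratorConfig",
    "generate_background_repertoire",
    "generate_background_sequences",
    "generate_epitope_repertoire",
    "generate_cohort",
    "generate_longitudinal_pair",
    "generate_sc_dataset",
]


@dataclass
class GeneratorConfig:
    """Shared knobs for the repertoire generators."""

    seed: int = 0
    n_clones: int = 500
    depth: int = 10_000
    clone_size_model: tuple = ("lognormal", 0.0, 2.0)  # or ("power_law", alpha)
    cdr3_length_range: tuple = (8, 20)
    aa_composition: np.ndarray | None = None  # 20-vector over AA_ALPHABET
    motif: tuple = ("GQP", 0.9, "center")  # (k-mer, planting prob, position policy)
    v_genes: list = field(default_factory=lambda: [f"TRBV{i}" for i in range(1, 31)])
    j_genes: list = field(default_factory=lambda: [f"TRBJ{i}-{j}" for i in (1, 2) for j in (1, 2, 3)])

    def __post_init__(self):
        if self.aa_composition is None:
            self.aa_composition = np.full(20, 1.0 / 20.0)
        self.aa_composition = np.asarray(self.aa_composition, dtype=float)
        if self.aa_composition.shape != (20,) or not np.isclose(self.aa_composition.sum(), 1.0):
            raise ArgumentError("aa_composition must be a 20-vector summing to 1")
        kmer, prob, policy = self.motif
        if not 0.0 <= prob <= 1.0:
            raise ArgumentError("motif planting probability must be in [0, 1]")
        if set(kmer) - set(AA_ALPHABET):
            raise ArgumentError(f"motif {kmer!r} contains non-standard residues")
        if policy not in ("center", "uniform-interior"):
            raise ArgumentError(f"unknown motif position policy {policy!r}")


# ---------------------------------------------------------------------------
# sequences and clone sizes
# ---------------------------------------------------------------------------

def _random_cdr3(cfg: GeneratorConfig, rng: np.random.Generator) -> str:
    lo, hi = cfg.cdr3_length_range
    length = int(rng.integers(lo, hi + 1))
    interior = rng.choice(list(AA_ALPHABET), size=length - 2, p=cfg.aa_composition)
    return "C" + "".join(interior) + "F"


def _plant_motif(seq: str, kmer: str, policy: str, rng: np.random.Generator) -> str:
    """Overwrite ``kmer`` into the CDR3 interior (never touching C.../...F)."""
    interior = seq[1:-1]
    k = len(kmer)
    if len(interior) < k:
        raise ArgumentError(f"motif {kmer!r} longer than CDR3 interior of {seq!r}")
    if policy == "center":
        start = (len(interior) - k) // 2
    else:  # uniform-interior
        start = int(rng.integers(0, len(interior) - k + 1))
    interior = interior[:start] + kmer + interior[start + k :]
    return "C" + interior + "F"


def generate_background_sequences(
    cfg: GeneratorConfig, n: int, rng: np.random.Generator | None = None, exclude_motif: str | None = None
) -> list[str]:
    """``n`` distinct background CDR3s, optionally rejecting a given k-mer."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        s = _random_cdr3(cfg, rng)
        if s in seen or (exclude_motif is not None and exclude_motif in s):
            continue
        seen.add(s)
        out.append(s)
    return out


def _clone_weights(cfg: GeneratorConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    model = cfg.clone_size_model
    if model[0] == "lognormal":
        _, mu, sigma = model
        w = rng.lognormal(mean=mu, sigma=sigma, size=n) if sigma > 0 else np.full(n, np.exp(mu))
    elif model[0] == "power_law":
        alpha = model[1]
        w = (np.arange(1, n + 1, dtype=float)) ** (-alpha)
        rng.shuffle(w)
    else:
        raise ArgumentError(f"unknown clone size model {model[0]!r}")
    return w / w.sum()


def _assemble_repertoire(
    cfg: GeneratorConfig,
    sample_id: str,
    seqs: list[str],
    counts: np.ndarray,
    rng: np.random.Generator,
    metadata: dict | None = None,
) -> Repertoire:
    df = pd.DataFrame(
        {
            "cdr3aa": seqs,
            "v_gene": rng.choice(cfg.v_genes, size=len(seqs)),
            "j_gene": rng.choice(cfg.j_genes, size=len(seqs)),
            "count": counts.astype(int),
        }
    )
    df = df[df["count"] > 0].reset_index(drop=True)
    return Repertoire(sample_id, df, metadata or {})


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_background_repertoire(cfg: GeneratorConfig, sample_id: str = "background") -> Repertoire:
    """One bulk TCRbeta sample: lognormal clone weights multinomially sampled
    to the configured read depth."""
    rng = np.random.default_rng(cfg.seed)
    seqs = generate_background_sequences(cfg, cfg.n_clones, rng)
    w = _clone_weights(cfg, cfg.n_clones, rng)
    counts = rng.multinomial(cfg.depth, w)
    return _assemble_repertoire(cfg, sample_id, seqs, counts, rng)


def generate_epitope_repertoire(
    cfg: GeneratorConfig, motif: tuple | None = None, n_positives: int = 200, subjects: int = 5
) -> TrainingSet:
    """Epitope-specific positives (with subject IDs) sharing a planted motif.

    Each positive carries the motif with the configured planting probability
    at the configured position policy; subjects are assigned round-robin so
    that leave-one-subject-out cross-validation is exercisable. The balanced
    background is drawn from the same sequence model without the motif.
    """
    kmer, prob, policy = motif if motif is not None else cfg.motif
    lo, _ = cfg.cdr3_length_range
    if len(kmer) > lo - 2:
        raise ArgumentError("motif longer than the minimum CDR3 interior")
    rng = np.random.default_rng(cfg.seed)
    raw = generate_background_sequences(cfg, n_positives, rng, exclude_motif=kmer)
    positives = []
    for i, seq in enumerate(raw):
        if rng.random() < prob:
            seq = _plant_motif(seq, kmer, policy, rng)
        positives.append((seq, f"subject{i % subjects:02d}"))
    pos_seqs = {p[0] for p in positives}
    background: list[str] = []
    while len(background) < len(positives):
        s = _random_cdr3(cfg, rng)
        if kmer in s or s in pos_seqs or s in background:
            continue
        background.append(s)
    return TrainingSet(epitope=f"synthetic_{kmer}", positives=positives, background=background)


def generate_cohort(
    cfg: GeneratorConfig,
    n_cases: int = 30,
    n_controls: int = 30,
    case_target_freq: float = 0.05,
    control_target_freq: float = 0.01,
) -> tuple[list[Repertoire], pd.DataFrame]:
    """Case/control repertoires differing in motif-bearing clone frequency.

    Background clones never contain the motif, so the injected clones carry
    exactly the labeled mass. Per-sample targets are jittered by +/-8% so
    realized frequencies stay within the +/-10% construction tolerance while
    null cohorts (equal targets) retain genuine between-sample variation.
    Returns the repertoires and a truth/cohort table (sample_id, group,
    target_frequency, n_target_clones, age, clonality, injected_keys).
    """
    for t in (case_target_freq, control_target_freq):
        if not 0.0 <= t < 1.0:
            raise ArgumentError("target frequencies must be in [0, 1)")
    kmer, _, policy = cfg.motif
    rng = np.random.default_rng(cfg.seed)
    reps, rows = [], []
    groups = ["case"] * n_cases + ["control"] * n_controls
    targets = [case_target_freq] * n_cases + [control_target_freq] * n_controls
    for i, (group, target) in enumerate(zip(groups, targets)):
        sample_id = f"{group}{i:03d}"
        seqs = generate_background_sequences(cfg, cfg.n_clones, rng, exclude_motif=kmer)
        w = _clone_weights(cfg, cfg.n_clones, rng)
        t_s = target * (1.0 + rng.uniform(-0.08, 0.08)) if target > 0 else 0.0
        m_reads = int(round(t_s * cfg.depth))
        bg_counts = rng.multinomial(cfg.depth - m_reads, w)
        if m_reads > 0:
            n_inj = max(1, int(round(cfg.n_clones * 0.02)))
            inj_seqs = [
                _plant_motif(s, kmer, policy, rng)
                for s in generate_background_sequences(cfg, n_inj, rng, exclude_motif=kmer)
            ]
            inj_counts = rng.multinomial(m_reads, _clone_weights(cfg, n_inj, rng))
        else:
            inj_seqs, inj_counts = [], np.array([], dtype=int)
        all_seqs = seqs + inj_seqs
        all_counts = np.concatenate([bg_counts, inj_counts])
        rep = _assemble_repertoire(cfg, sample_id, all_seqs, all_counts, rng, metadata={"group": group})
        injected = set(inj_seqs) & set(rep.clonotypes["cdr3aa"])
        realized = float(rep.clonotypes.loc[rep.clonotypes["cdr3aa"].isin(injected), "frequency"].sum())
        age = float(rng.normal(63, 10)) if group == "case" else float(rng.normal(52, 12))
        p = rep.frequencies
        clon = 1.0 - float(-(p[p > 0] * np.log(p[p > 0])).sum()) / np.log(rep.richness)
        rep.metadata["age"] = age
        reps.append(rep)
        rows.append((sample_id, group, realized, len(injected), age, clon, sorted(injected)))
    truth = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "target_frequency", "n_target_clones", "age", "clonality", "injected_keys"],
    )
    return reps, truth


def generate_longitudinal_pair(
    cfg: GeneratorConfig, n_expanded: int = 20, fold: float = 10.0, replacing_fraction: float = 0.1
) -> tuple[Repertoire, Repertoire, dict]:
    """Pre/post sample pair with planted expansions and replacing clones.

    Post frequencies are the pre frequencies with ``n_expanded`` clones
    multiplied by ``fold`` and renormalized, plus novel clones carrying
    ``replacing_fraction`` of the post mass; both samples are multinomially
    resampled to the configured depth. Expansions are planted only in clones
    with baseline frequency >= 5/depth (smaller clones cannot reach
    significance at the study depth). The truth table lists the planted
    expanded keys and the realized replacing keys (novel clones surviving
    resampling).
    """
    if fold <= 1.0:
        raise ArgumentError("expansion fold must exceed 1")
    if not 0.0 <= replacing_fraction < 1.0:
        raise ArgumentError("replacing_fraction must be in [0, 1)")
    if n_expanded >= cfg.n_clones:
        raise ArgumentError("n_expanded must be smaller than n_clones")
    rng = np.random.default_rng(cfg.seed)
    seqs = generate_background_sequences(cfg, cfg.n_clones, rng)
    w = _clone_weights(cfg, cfg.n_clones, rng)
    eligible = np.where(w >= 5.0 / cfg.depth)[0]
    if eligible.size < n_expanded:
        raise ArgumentError(f"only {eligible.size} clones large enough to plant {n_expanded} expansions")
    planted = rng.choice(eligible, size=n_expanded, replace=False)
    post_w = w.copy()
    post_w[planted] *= fold
    post_w /= post_w.sum()

    n_novel = max(1, int(round(replacing_fraction * cfg.n_clones))) if replacing_fraction > 0 else 0
    novel_seqs = []
    if n_novel:
        seen = set(seqs)
        while len(novel_seqs) < n_novel:
            s = _random_cdr3(cfg, rng)
            if s not in seen:
                seen.add(s)
                novel_seqs.append(s)
        novel_w = _clone_weights(cfg, n_novel, rng) * replacing_fraction
        post_w = np.concatenate([post_w * (1.0 - replacing_fraction), novel_w])

    pre_counts = rng.multinomial(cfg.depth, w)
    post_counts = rng.multinomial(cfg.depth, post_w)

    vj_rng = np.random.default_rng(cfg.seed + 1)
    all_seqs = seqs + novel_seqs
    v = vj_rng.choice(cfg.v_genes, size=len(all_seqs))
    j = vj_rng.choice(cfg.j_genes, size=len(all_seqs))

    def build(sample_id, counts, n_rows):
        df = pd.DataFrame(
            {"cdr3aa": all_seqs[:n_rows], "v_gene": v[:n_rows], "j_gene": j[:n_rows], "count": counts}
        )
        df = df[df["count"] > 0].reset_index(drop=True)
        return Repertoire(sample_id, df, {"timepoint": sample_id})

    pre = build("pre", pre_counts, cfg.n_clones)
    post = build("post", post_counts, len(all_seqs))
    key = lambda i: f"{all_seqs[i]}|{v[i]}"
    post_keys = set(post.keys("cdr3_v"))
    truth = {
        "expanded_keys": sorted(key(i) for i in planted),
        "replacing_keys": sorted(
            k for k in (key(cfg.n_clones + i) for i in range(n_novel)) if k in post_keys
        ),
        "fold": fold,
        "replacing_fraction": replacing_fraction,
    }
    return pre, post, truth


def generate_sc_dataset(
    cfg: GeneratorConfig,
    n_cells: int = 600,
    cluster_sizes: dict | None = None,
    enrichment: tuple | None = ("MAA", "exhausted", 20.0),
    de: list | None = None,
    lr: list | None = None,
    n_genes: int = 100,
    baseline_mean: float = 0.5,
    dispersion: float = 0.5,
    frac_no_tcr: float = 0.1,
) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Clustered single-cell counts with planted enrichment, DE and LR effects.

    Counts are negative binomial (gamma-Poisson) with cluster-specific means
    and fixed dispersion. ``enrichment`` plants specificity labels with the
    given odds in the target cluster (baseline label probability 0.05
    elsewhere); ``de`` entries (gene, cluster, shift) multiply the gene's mean
    by exp(shift) in that cluster; ``lr`` entries (ligand, receptor, clusterA,
    clusterB, strength) set the ligand mean in A and receptor mean in B to
    ``strength`` (0.02 elsewhere). The truth dict records every planted effect.
    """
    rng = np.random.default_rng(cfg.seed)
    if cluster_sizes is None:
        base = n_cells // 3
        cluster_sizes = {"stemlike": base, "exhausted": base, "treg": n_cells - 2 * base}
    if sum(cluster_sizes.values()) != n_cells:
        raise ArgumentError("cluster sizes must sum to n_cells")
    de = de or []
    lr = lr or []

    clusters = np.concatenate([[cl] * n for cl, n in cluster_sizes.items()])
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]

    genes = [f"G{i:04d}" for i in range(n_genes)]
    extra = []
    for g, _, _ in de:
        if g not in genes and g not in extra:
            extra.append(g)
    for ligand, receptor, *_ in lr:
        for g in (ligand, receptor):
            if g not in genes and g not in extra:
                extra.append(g)
    genes = genes + extra

    lr_genes = {g for ligand, receptor, *_ in lr for g in (ligand, receptor)}
    means = np.full((len(genes), n_cells), baseline_mean)
    gi = {g: i for i, g in enumerate(genes)}
    for g in lr_genes:
        means[gi[g], :] = 0.02
    for g, cl, shift in de:
        means[gi[g], clusters == cl] *= np.exp(shift)
    for ligand, receptor, cl_a, cl_b, strength in lr:
        means[gi[ligand], clusters == cl_a] = strength
        means[gi[receptor], clusters == cl_b] = strength

    lam = rng.gamma(shape=1.0 / dispersion, scale=means * dispersion)
    counts = rng.poisson(lam).astype(float)
    matrix = ExpressionMatrix(counts, genes, cell_ids, layer="counts")

    # clonotype links and specificity labels
    has_tcr = rng.random(n_cells) >= frac_no_tcr
    clonotype = np.where(has_tcr, [f"CASS{i:05d}F|TRBV9" for i in range(n_cells)], None)
    specificity = np.array(["none"] * n_cells, dtype=object)
    if enrichment is not None:
        label, target_cluster, odds = enrichment
        p0 = 0.05
        odds0 = p0 / (1 - p0)
        p1 = odds * odds0 / (1 + odds * odds0)
        prob = np.where(clusters == target_cluster, p1, p0)
        hit = (rng.random(n_cells) < prob) & has_tcr
        specificity[hit] = label
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cluster": clusters,
            "clonotype_key": clonotype,
            "specificity": specificity,
            "sample_id": "sc_sample",
        }
    )
    truth = {"enrichment": enrichment, "de": de, "lr": lr, "cluster_sizes": cluster_sizes}
    return matrix, cells, truth


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Copy of a config with a different seed (convenience for replicates)."""
    return replace(cfg, seed=seed)
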