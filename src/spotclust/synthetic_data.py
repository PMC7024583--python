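"""Synthetic spot matrices with known tree structure and planted markers.

The generator emulates the structure of a multi-species 2D-gel survey:
~800 protein spots scored present/absent in ~50 samples from 10 species
arranged in a known hierarchy. Three spot classes are produced:

* **background** spots evolve independently along the model tree as a
  two-state (absent/present) continuous-time Markov chain with gain rate
  ``lambda01`` and loss rate ``lambda10`` per unit branch length and a
  Bernoulli(``root_prob``) root state — so Jaccard distances between
  species genuinely reflect tree distances, the property the whole
  downstream analysis presumes;
* **planted markers**: spots present in exactly the species of a chosen
  clade and absent elsewhere (perfect markers, ground truth for the
  indicator-value screen);
* **factor blocks**: spots private to one level of a sample-level factor
  (e.g. body part or collection location), mimicking non-phylogenetic
  structure in real samples.

Samples inherit their species' spot row and are then perturbed by
independent false-negative (present cell dropped) and false-positive
(absent cell gained) detection noise. Every spot carries a provenance
label, and the pre-noise truth is returned alongside the data, so
recovery of trees, markers and stable clusters can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from skbio import TreeNode

from spotclust.spot_data import SampleAnnotation, SpotMatrix
from spotclust.trees import read_newick

DEFAULT_TREE = (
    "(((L_ard:1.0,L_mel:1.0)Littoraria:1.0,"
    "(E_mil:0.8,E_mar:0.8)Echinolittorina:1.2):0.5,"
    "(L_lit:1.8,((L_obt:0.7,L_fab:0.7)obt_group:0.6,"
    "((L_sax:0.25,L_arc:0.25)sax_arc:0.45,L_com:0.7)sax_group:0.6)"
    "Neritrema:0.5)Littorina:0.7);"
)

#: species -> higher-clade factors for the default taxonomy
DEFAULT_SPECIES_FACTORS = {
    "L_ard": dict(genus="Littoraria", subgenus="", species_group=""),
    "L_mel": dict(genus="Littoraria", subgenus="", species_group=""),
    "E_mil": dict(genus="Echinolittorina", subgenus="", species_group=""),
    "E_mar": dict(genus="Echinolittorina", subgenus="", species_group=""),
    "L_lit": dict(genus="Littorina", subgenus="Littorina", species_group=""),
    "L_obt": dict(genus="Littorina", subgenus="Neritrema", species_group="obtusata"),
    "L_fab": dict(genus="Littorina", subgenus="Neritrema", species_group="obtusata"),
    "L_sax": dict(genus="Littorina", subgenus="Neritrema", species_group="saxatilis"),
    "L_arc": dict(genus="Littorina", subgenus="Neritrema", species_group="saxatilis"),
    "L_com": dict(genus="Littorina", subgenus="Neritrema", species_group="saxatilis"),
}

DEFAULT_LOCATIONS = {
    "L_sax": ["Ru", "UK", "No", "Fr"],
    "L_arc": ["Ru", "UK", "No"],
    "L_com": ["UK", "Fr"],
    "L_obt": ["Ru", "UK", "No", "Fr"],
    "L_fab": ["Ru", "UK", "Fr"],
    "L_lit": ["Ru", "Fr"],
    "L_ard": ["Cn"],
    "L_mel": ["Cn"],
    "E_mil": ["Cn", "Il"],
    "E_mar": ["Il"],
}

DEFAULT_N_SAMPLES = {
    "L_sax": 8, "L_arc": 6, "L_com": 4, "L_obt": 6, "L_fab": 5,
    "L_lit": 4, "L_ard": 4, "L_mel": 4, "E_mil": 4, "E_mar": 4,
}

DEFAULT_MARKER_PLAN = [
    ("L_ard", ("L_ard",), 10), ("L_mel", ("L_mel",), 10),
    ("E_mil", ("E_mil",), 10), ("E_mar", ("E_mar",), 10),
    ("L_lit", ("L_lit",), 10), ("L_obt", ("L_obt",), 10),
    ("L_fab", ("L_fab",), 10), ("L_sax", ("L_sax",), 10),
    ("L_arc", ("L_arc",), 10), ("L_com", ("L_com",), 10),
    ("Littoraria", ("L_ard", "L_mel"), 8),
    ("Echinolittorina", ("E_mil", "E_mar"), 8),
    ("sax_arc", ("L_sax", "L_arc"), 4),
    ("sax_group", ("L_sax", "L_arc", "L_com"), 8),
    ("obt_group", ("L_obt", "L_fab"), 8),
    ("Neritrema", ("L_obt", "L_fab", "L_sax", "L_arc", "L_com"), 16),
    ("Littorina", ("L_lit", "L_obt", "L_fab", "L_sax", "L_arc", "L_com"), 8),
]

DEFAULT_FACTOR_PLAN = [
    ("body_part", "pe", 20),
    ("location", "UK", 16),
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic spot-matrix generator.

    The defaults mirror the scale of a 10-species littorinid survey:
    796 spots (600 background + 160 planted clade markers + 36
    factor-block spots) by 49 samples, with low detection noise.
    """

    tree: str = DEFAULT_TREE
    n_samples: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_SAMPLES))
    m_background: int = 600
    gain_rate: float = 0.35  # lambda01 per unit branch length
    loss_rate: float = 0.35  # lambda10 per unit branch length
    root_prob: float = 0.5
    fn_rate: float = 0.02  # false-negative detection probability
    fp_rate: float = 0.005  # false-positive detection probability
    marker_plan: list[tuple[str, tuple[str, ...], int]] = field(
        default_factory=lambda: list(DEFAULT_MARKER_PLAN)
    )
    factor_plan: list[tuple[str, str, int]] = field(
        default_factory=lambda: list(DEFAULT_FACTOR_PLAN)
    )
    locations: dict[str, list[str]] = field(
        default_factory=lambda: dict(DEFAULT_LOCATIONS)
    )
    species_factors: dict[str, dict[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_FACTORS)
    )
    seed: int = 0

    def __post_init__(self):
        for r in (self.gain_rate, self.loss_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        for p in (self.root_prob, self.fn_rate, self.fp_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        self.marker_plan = [(n, tuple(c), int(k)) for n, c, k in self.marker_plan]
        self.factor_plan = [(f, l, int(k)) for f, l, k in self.factor_plan]

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Load a configuration from a YAML (or JSON) mapping; omitted keys
        keep their defaults."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**data)


def noiseless_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Default configuration with detection noise and factor blocks off —
    the perfect-data regime in which the pipeline must recover everything
    exactly."""
    kw = dict(fn_rate=0.0, fp_rate=0.0, factor_plan=[], seed=seed)
    kw.update(overrides)
    return GeneratorConfig(**kw)


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated data set."""

    tree: TreeNode
    spot_ids: list[str]
    provenance: list[str]  # background | marker:<clade> | factor:<factor>=<level>
    species_matrix: SpotMatrix  # pre-noise spots x species
    marker_clades: dict[str, tuple[str, ...]]  # clade name -> species tuple

    def true_perfect_markers(self, clade_species: tuple[str, ...]) -> list[str]:
        """Spots whose pre-noise species pattern is exactly the clade
        indicator (planted markers plus background spots that happened to
        evolve that pattern)."""
        sm = self.species_matrix
        want = np.array([s in set(clade_species) for s in sm.sample_ids], dtype=np.int8)
        hit = (sm.values == want[None, :]).all(axis=1)
        return [sid for sid, h in zip(sm.spot_ids, hit) if h]


def _clade_node(tree: TreeNode, species: tuple[str, ...]) -> None:
    """Validate that ``species`` forms a clade (or the whole tip set)."""
    tipsets = {frozenset(x.name for x in nd.tips()) for nd in tree.non_tips(include_self=True)}
    tipsets |= {frozenset((x.name,)) for x in tree.tips()}
    if frozenset(species) not in tipsets:
        raise ValueError(f"{tuple(species)} is not a clade of the model tree")


def simulate_spot_evolution(cfg: GeneratorConfig, rng=None):
    """Species-level presence matrix plus ground truth.

    Background spots follow the two-state CTMC along the tree: with total
    rate s = lambda01 + lambda10 the transition probabilities over a
    branch of length t are P(0->1) = (lambda01/s)(1 - exp(-s t)) and
    P(1->0) = (lambda10/s)(1 - exp(-s t)).
    """
    rng = np.random.default_rng([cfg.seed, 1]) if rng is None else rng
    tree = read_newick(cfg.tree)
    species = [x.name for x in tree.tips()]
    n_sp = len(species)
    col = {s: i for i, s in enumerate(species)}

    lam01, lam10 = cfg.gain_rate, cfg.loss_rate
    s = lam01 + lam10
    mb = cfg.m_background

    state: dict[TreeNode, np.ndarray] = {}
    bg = np.zeros((mb, n_sp), dtype=np.int8)
    root_state = (rng.random(mb) < cfg.root_prob).astype(np.int8)
    for node in tree.preorder():
        if node.is_root():
            state[node] = root_state
            continue
        t = node.length or 0.0
        if s > 0:
            pchange = 1.0 - np.exp(-s * t)
            p01 = (lam01 / s) * pchange
            p10 = (lam10 / s) * pchange
        else:
            p01 = p10 = 0.0
        parent = state[node.parent]
        u = rng.random(mb)
        st = np.where(parent == 1, (u >= p10), (u < p01)).astype(np.int8)
        state[node] = st
        if node.is_tip():
            bg[:, col[node.name]] = st

    rows = [bg]
    spot_ids = [f"bg{i:04d}" for i in range(mb)]
    provenance = ["background"] * mb
    marker_clades = {}
    for name, clade, count in cfg.marker_plan:
        _clade_node(tree, clade)
        marker_clades[name] = tuple(clade)
        want = np.array([sp in set(clade) for sp in species], dtype=np.int8)
        rows.append(np.tile(want, (count, 1)))
        spot_ids += [f"mk_{name}_{i:02d}" for i in range(count)]
        provenance += [f"marker:{name}"] * count
    for factor, level, count in cfg.factor_plan:
        rows.append(np.zeros((count, n_sp), dtype=np.int8))
        spot_ids += [f"fx_{factor}_{level}_{i:02d}" for i in range(count)]
        provenance += [f"factor:{factor}={level}"] * count

    mat = SpotMatrix(spot_ids, species, np.vstack(rows))
    return mat, SyntheticTruth(tree, spot_ids, provenance, mat, marker_clades)


def _annotation_rows(cfg: GeneratorConfig):
    rows = []
    for sp in sorted(cfg.n_samples):
        locs = cfg.locations.get(sp, ["loc1"])
        higher = cfg.species_factors.get(
            sp, dict(genus="", subgenus="", species_group="")
        )
        for i in range(cfg.n_samples[sp]):
            rows.append(
                dict(
                    sample_id=f"{sp}_{i:02d}",
                    species=sp,
                    location=locs[i % len(locs)],
                    sex="f" if i % 2 == 0 else "m",
                    body_part="pe" if i % 4 == 3 else "so",
                    **higher,
                )
            )
    return rows


def simulate_samples(species_matrix: SpotMatrix, cfg: GeneratorConfig, rng=None):
    """Expand a species matrix to noisy per-sample detections.

    Each sample copies its species row; factor-block spots are set present
    in exactly the samples of their factor level; then every cell flips
    1->0 with ``fn_rate`` and 0->1 with ``fp_rate`` independently.
    """
    rng = np.random.default_rng([cfg.seed, 2]) if rng is None else rng
    import pandas as pd

    rows = _annotation_rows(cfg)
    ann = SampleAnnotation(pd.DataFrame(rows))
    samples = ann.sample_ids
    sp_col = {s: j for j, s in enumerate(species_matrix.sample_ids)}

    vals = np.column_stack(
        [species_matrix.values[:, sp_col[ann.factor("species")[s]]] for s in samples]
    ).astype(np.int8)

    spot_index = {sid: i for i, sid in enumerate(species_matrix.spot_ids)}
    for factor, level, count in cfg.factor_plan:
        members = np.array([ann.factor(factor)[s] == level for s in samples])
        for i in range(count):
            sid = f"fx_{factor}_{level}_{i:02d}"
            vals[spot_index[sid], :] = members.astype(np.int8)

    u = rng.random(vals.shape)
    flipped = np.where(vals == 1, (u >= cfg.fn_rate), (u < cfg.fp_rate)).astype(np.int8)
    return SpotMatrix(species_matrix.spot_ids, samples, flipped), ann


def generate(cfg: GeneratorConfig):
    """One-call generator: (sample SpotMatrix, SampleAnnotation, SyntheticTruth)."""
    sp_mat, truth = simulate_spot_evolution(cfg)
    samples, ann = simulate_samples(sp_mat, cfg)
    return samples, ann, truth


def planted_targets(truth: SyntheticTruth, ann: SampleAnnotation):
    """TargetCluster objects for every planted marker clade."""
    from spotclust.indval import TargetCluster

    targets = []
    species = ann.factor("species")
    for name, clade in truth.marker_clades.items():
        members = [s for s in ann.sample_ids if species[s] in set(clade)]
        targets.append(TargetCluster(name, members))
    return targets


def end_to_end_recovery(
    cfg: GeneratorConfig,
    alpha: float = 0.05,
    n_perm: int = 9_999,
    stability_b: int = 500,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline on generated data and score it against truth.

    Reports the Robinson-Foulds distance between the inferred species NJ
    tree and the model tree, precision/recall of perfect-marker discovery
    at the given FDR level (scored against the set of spots whose
    pre-noise species pattern exactly matches each target clade), and the
    bootstrap stability of the true species clusters at k = n_species.
    """
    from spotclust.dissimilarity import jaccard_binary
    from spotclust.indval import marker_table
    from spotclust.spot_data import consensus_proteomes
    from spotclust.stability import bootstrap_cluster_stability
    from spotclust.treecmp import robinson_foulds
    from spotclust.trees import neighbor_joining

    seed = cfg.seed if seed is None else seed
    samples, ann, truth = generate(cfg)

    consensus = consensus_proteomes(samples, ann, "species")
    sp_tree = neighbor_joining(jaccard_binary(consensus))
    rf, nrf = robinson_foulds(sp_tree, truth.tree)

    targets = planted_targets(truth, ann)
    records, summary = marker_table(samples, targets, alpha=alpha, n_perm=n_perm, seed=seed)
    pred = set(
        map(tuple, records.loc[records["is_perfect"], ["target", "spot_id"]].to_numpy())
    )
    true_pairs = set()
    for name, clade in truth.marker_clades.items():
        for sid in truth.true_perfect_markers(clade):
            true_pairs.add((name, sid))
    tp = len(pred & true_pairs)
    precision = tp / len(pred) if pred else (1.0 if not true_pairs else 0.0)
    recall = tp / len(true_pairs) if true_pairs else 1.0

    # power of the screen on the planted spots, regardless of whether noise
    # broke their perfection: fraction flagged significant for their clade
    sig = set(
        map(tuple, records.loc[records["is_marker"], ["target", "spot_id"]].to_numpy())
    )
    planted_pairs = {
        (name, sid)
        for name in truth.marker_clades
        for sid, prov in zip(truth.spot_ids, truth.provenance)
        if prov == f"marker:{name}"
    }
    sig_recall = (
        len(sig & planted_pairs) / len(planted_pairs) if planted_pairs else 1.0
    )

    n_species = len(set(ann.factor("species")))
    stab = bootstrap_cluster_stability(
        samples, k_range=[n_species], b=stability_b, seed=seed
    )
    species_of = ann.factor("species")
    same_species = [
        r for r in stab if r.members and len({species_of[s] for s in r.members}) == 1
    ]
    return {
        "rf": rf,
        "nrf": nrf,
        "inferred_tree": sp_tree,
        "marker_precision": precision,
        "marker_recall": recall,
        "planted_marker_significant_recall": sig_recall,
        "n_planted_markers": len(planted_pairs),
        "n_true_perfect_markers": len(true_pairs),
        "n_predicted_perfect_markers": len(pred),
        "marker_summary": summary,
        "stability_records": stab,
        "min_species_cluster_mean_j": (
            min(r.mean_j for r in same_species) if same_species else np.nan
        ),
        "n_species_clusters": len(same_species),
    }
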