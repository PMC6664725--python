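"""Desk-scale synthetic drug-screen corpora with a planted signal.

Emits the three CSV tables of the GDSC-style schema (drug list + SMILES
mapping, binary cell-line features, long-format log-IC50) from a generative
model with a known, recoverable structure-activity function:

    log-IC50(d, c) = baseline
                     + sum_m motif_effect[m] * motif_present(d, m)
                     + sum_k feature_effect[k] * feature(c, k)
                     + interaction_strength * motif_present(d, 0) * feature(c, 0)
                     + Gaussian noise

Drugs are random SMILES-like token strings into which short token motifs
are planted; putting the drug signal in *contiguous* motifs (rather than
global token counts) means a model can only pick it up by pattern-matching
along the string — exactly what the 1D convolutional drug branch is built
to do.  Cell lines are random binary feature vectors with a handful of
causal features.  Noise lives on the log-IC50 scale, before normalization.

Marginals mirror a real screen: roughly 80% of the drug x cell grid is
measured and 37% of measurements fall below the maximum screening
concentration.  The same seed always reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = ["SyntheticConfig", "SyntheticCorpus", "generate", "ground_truth"]

_DEFAULT_ALPHABET = (
    "C", "c", "N", "n", "O", "o", "S", "F", "Cl", "Br",
    "=", "#", "(", ")", "1", "2", "3", "[nH]", "[O-]", "[N+]",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings; defaults define the standard desk-scale corpus."""

    n_drugs: int = 60
    n_cells: int = 120
    n_features: int = 120
    smiles_len_range: tuple[int, int] = (20, 60)
    token_alphabet: tuple[str, ...] = _DEFAULT_ALPHABET
    n_motifs: int = 3
    motif_len: int = 4
    motif_prob: float = 0.5
    motif_effects: tuple[float, ...] = (-2.5, 1.8, -1.2)
    feature_effects: tuple[float, ...] = (1.5, -1.5, 1.0, -1.0, 0.8, -0.8)
    feature_prob: float = 0.3
    baseline: float = -2.0
    interaction_strength: float = 1.0
    noise_sd: float = 0.25
    known_density: float = 0.8
    below_max_conc_prob: float = 0.37
    tissues: tuple[str, ...] = ("lung", "blood", "breast",
                                "skin", "bone", "digestive")
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.motif_effects) != self.n_motifs:
            raise ValueError("motif_effects length must equal n_motifs")
        if len(self.feature_effects) > self.n_features:
            raise ValueError("more feature effects than features")
        if not 0.0 < self.known_density <= 1.0:
            raise ValueError("known_density must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.smiles_len_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid smiles_len_range")
        if hi < self.motif_len:
            raise ValueError("motifs cannot fit into the longest SMILES")


@dataclass
class SyntheticCorpus:
    """Generated corpus: file paths plus the realized ground-truth state."""

    config: SyntheticConfig
    drug_list_path: Path
    smiles_map_path: Path
    cell_features_path: Path
    ic50_path: Path
    manifest_path: Path
    motifs: list[list[str]]
    drug_motifs: dict[str, np.ndarray] = field(repr=False)   # id -> indicator
    cell_features: dict[str, np.ndarray] = field(repr=False)  # id -> binary vec


def _contains_motif(tokens: list[str], motif: list[str]) -> bool:
    m = len(motif)
    return any(tokens[i:i + m] == motif for i in range(len(tokens) - m + 1))


def _feature_names(n_features: int) -> list[str]:
    n_mut = round(n_features * 0.42)  # mutation states, then copy-number calls
    return ([f"mut_{i:04d}" for i in range(n_mut)]
            + [f"cna_{i:04d}" for i in range(n_features - n_mut)])


def ground_truth(corpus: SyntheticCorpus, drug_id: str, cell_id: str) -> float:
    """Noiseless log-IC50 of the generative model for one pair."""
    cfg = corpus.config
    try:
        ind = corpus.drug_motifs[drug_id]
    except KeyError:
        raise KeyError(f"unknown drug {drug_id!r}") from None
    try:
        feats = corpus.cell_features[cell_id]
    except KeyError:
        raise KeyError(f"unknown cell line {cell_id!r}") from None
    k = len(cfg.feature_effects)
    value = (cfg.baseline
             + float(np.dot(cfg.motif_effects, ind))
             + float(np.dot(cfg.feature_effects, feats[:k])))
    if cfg.n_motifs and cfg.n_features:
        value += cfg.interaction_strength * float(ind[0]) * float(feats[0])
    return value


def generate(config: SyntheticConfig, out_dir: str | Path) -> SyntheticCorpus:
    """Write the four CSV files plus a manifest; return the realized corpus."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alphabet = list(config.token_alphabet)

    # Distinct token motifs carrying the drug-side signal.
    motifs: list[list[str]] = []
    guard = 0
    while len(motifs) < config.n_motifs:
        cand = [alphabet[i] for i in
                rng.integers(0, len(alphabet), size=config.motif_len)]
        if cand not in motifs:
            motifs.append(cand)
        guard += 1
        if guard > 1000 * max(config.n_motifs, 1):
            raise RuntimeError("could not place distinct motifs; "
                               "enlarge the alphabet or shorten motifs")

    lo, hi = config.smiles_len_range
    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    smiles: dict[str, str] = {}
    drug_motifs: dict[str, np.ndarray] = {}
    for d in drug_ids:
        base_len = int(rng.integers(lo, hi + 1))
        tokens = [alphabet[i] for i in
                  rng.integers(0, len(alphabet), size=base_len)]
        for m, motif in enumerate(motifs):
            if rng.random() < config.motif_prob:
                pos = int(rng.integers(0, len(tokens) + 1))
                tokens[pos:pos] = motif
        smiles[d] = "".join(tokens)
        # Presence is re-detected on the final string so accidental motif
        # occurrences count toward the signal exactly as planted ones do.
        drug_motifs[d] = np.array(
            [_contains_motif(tokens, m) for m in motifs], dtype=np.uint8)

    cell_ids = [f"C{i:04d}" for i in range(config.n_cells)]
    feats_matrix = (rng.random((config.n_cells, config.n_features))
                    < config.feature_prob).astype(np.uint8)
    cell_features = {c: feats_matrix[j] for j, c in enumerate(cell_ids)}
    tissues = {c: config.tissues[j % len(config.tissues)]
               for j, c in enumerate(cell_ids)}

    drug_list_path = out / "drug_list.csv"
    drug_list_path.write_text(
        "drug_id,name\n"
        + "".join(f"{d},compound-{d}\n" for d in drug_ids))
    smiles_map_path = out / "smiles_map.csv"
    smiles_map_path.write_text(
        "drug_id,canonical_smiles\n"
        + "".join(f"{d},{smiles[d]}\n" for d in drug_ids))

    names = _feature_names(config.n_features)
    lines = ["cell_id,tissue," + ",".join(names)]
    for c in cell_ids:
        lines.append(f"{c},{tissues[c]}," +
                     ",".join(str(int(v)) for v in cell_features[c]))
    cell_features_path = out / "cell_features.csv"
    cell_features_path.write_text("\n".join(lines) + "\n")

    corpus = SyntheticCorpus(
        config=config,
        drug_list_path=drug_list_path, smiles_map_path=smiles_map_path,
        cell_features_path=cell_features_path, ic50_path=out / "ic50.csv",
        manifest_path=out / "manifest.json",
        motifs=motifs, drug_motifs=drug_motifs, cell_features=cell_features,
    )

    rows = ["drug_id,cell_id,log_ic50,below_max_conc"]
    for d in drug_ids:
        for c in cell_ids:
            if rng.random() >= config.known_density:
                continue
            x = ground_truth(corpus, d, c)
            if config.noise_sd > 0:
                x += rng.normal(0.0, config.noise_sd)
            flag = int(rng.random() < config.below_max_conc_prob)
            rows.append(f"{d},{c},{x:.6f},{flag}")
    corpus.ic50_path.write_text("\n".join(rows) + "\n")

    manifest = {
        "config": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in asdict(config).items()},
        "motifs": motifs,
        "drug_motifs": {d: drug_motifs[d].tolist() for d in drug_ids},
        "smiles": smiles,
    }
    corpus.manifest_path.write_text(json.dumps(manifest, indent=1))
    return corpus
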