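"""Full affinity predictor: featurization, forward pass, training, metrics.

Per complex, the static (non-learned) features are computed once — the
sampled pocket surface with its atom neighborhoods and curvatures, the
residue graph, the frozen sequence embedding, the ligand graph, and the
bipartite contact graph — and the trainable model consumes them:

    surface  -> quasi-geodesic conv embedding -> adapter -> tokens
    structure-> GVP-GNN scalar tokens         -> adapter -> tokens
    sequence -> frozen embedding              -> adapter -> tokens
    fusion   -> encoder/decoder cross-attention -> pooled 3d vector
    ligand   -> attentive molecular graph embedding
    contacts -> interaction embedding
    head     -> MLP on the concatenation -> scalar -log affinity

Training minimizes the mean squared error with Adam; model selection is
by best validation RMSE.  Evaluation reports RMSE, MAE, the Pearson
correlation R, and the regression standard deviation

    SD = sqrt( sum_i (y_i - (a + b yhat_i))^2 / (N - 2) ),

with (a, b) the least-squares fit of y on yhat — the affine-invariant
spread around the regression line conventional in affinity benchmarks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .data_io import ATOM_VOCAB_6, ATOM_VOCAB_22, AffinityRecord, AtomCloud, LigandStructure
from .fusion import FusionModule, project_embeddings_2d
from .interaction import HeteroGraph, InteractionEncoder, build_hetero_graph
from .ligand import LigandEncoder, LigandGraph, featurize_ligand
from .nn import MLP, Adam, Linear, Module, Tensor, concatenate
from .sequence import FallbackEmbedder, ProtBertEmbedder, embed_sequence
from .structure import ResidueGraph, StructureEncoder, build_residue_graph
from .surface import (
    SurfaceEncoder,
    chemical_neighborhoods,
    geometric_features,
    quasi_geodesic_distances,
    sample_surface,
    select_pocket,
)
from .synthetic import SyntheticComplex

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexFeatures", "MetricsReport", "AffinityModel",
    "featurize_complex", "featurize_synthetic",
    "mse_loss", "evaluate", "train", "alignment_dispersion",
]


@dataclass
class ComplexFeatures:
    """Static per-complex inputs to the trainable model."""

    chem_onehot: np.ndarray  # (K, k_atoms, n_types)
    chem_inv_dist: np.ndarray  # (K, k_atoms)
    curvatures: np.ndarray  # (K, 2 * n_scales)
    qg_dist: np.ndarray  # (K, K) quasi-geodesic distances
    residue_graph: ResidueGraph
    sequence_tokens: np.ndarray  # (L, seq_width), frozen
    ligand_graph: LigandGraph
    hetero: HeteroGraph
    hetero_protein_features: np.ndarray  # (n_p, n_types) one-hot atom types
    complex_id: str = ""


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    sd: float
    r: float
    n: int

    def __post_init__(self):
        if np.isfinite(self.rmse) and np.isfinite(self.mae) and self.rmse + 1e-12 < self.mae:
            raise ValueError("RMSE cannot be smaller than MAE")

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "sd": self.sd, "r": self.r, "n": self.n}


# --------------------------------------------------------------------------
# featurization
# --------------------------------------------------------------------------

def make_sequence_backend(config: RunConfig):
    if config.sequence.backend == "fallback":
        return FallbackEmbedder(
            width=config.sequence.width, window=config.sequence.window, seed=config.sequence.seed
        )
    if config.sequence.backend == "protbert":
        return ProtBertEmbedder()
    raise ValueError(f"unknown sequence backend {config.sequence.backend!r}")


def featurize_complex(
    protein: AtomCloud,
    sequence: str,
    ligand: LigandStructure | LigandGraph,
    config: RunConfig,
    seed: int = 0,
    sequence_backend=None,
    complex_id: str = "",
) -> ComplexFeatures:
    """Compute every static model input for one complex."""
    lig_graph = ligand if isinstance(ligand, LigandGraph) else featurize_ligand(ligand.mol, ligand.coords)

    surf = sample_surface(protein, resolution=config.surface.resolution, seed=seed,
                          level=config.surface.level)
    pocket = select_pocket(surf, lig_graph.center, config.surface.pocket_k)

    vocab = ATOM_VOCAB_22 if config.surface.atom_types == 22 else ATOM_VOCAB_6
    if len(protein.vocab) != len(vocab):
        # re-index atoms under the requested vocabulary
        protein = AtomCloud(
            coords=protein.coords,
            atom_type=np.array([_reindex(e, vocab) for e in protein.element], dtype=np.intp),
            residue_index=protein.residue_index,
            chain_id=protein.chain_id,
            atom_name=protein.atom_name,
            element=protein.element,
            res_name=protein.res_name,
            vocab=vocab,
        )
    onehot, inv_dist = chemical_neighborhoods(pocket.points, protein, config.surface.k_atoms)
    curv = geometric_features(surf, indices=pocket.indices)
    qg = quasi_geodesic_distances(pocket.points, pocket.normals)

    res_graph = build_residue_graph(
        protein, lig_graph.coords,
        pocket_radius=config.structure.pocket_radius,
        k_neighbors=config.structure.k_neighbors,
    )

    backend = sequence_backend if sequence_backend is not None else make_sequence_backend(config)
    seq_emb = embed_sequence(sequence, backend)

    if config.interaction.protein_scope == "pocket":
        mask = np.isin(protein.residue_index, res_graph.residue_ids)
    else:
        mask = np.ones(len(protein), dtype=bool)
    prot_coords = protein.coords[mask]
    hetero = build_hetero_graph(lig_graph.coords, prot_coords, cutoff=config.interaction.cutoff)
    prot_feats = np.eye(len(protein.vocab))[protein.atom_type[mask]]

    return ComplexFeatures(
        chem_onehot=onehot,
        chem_inv_dist=inv_dist,
        curvatures=curv,
        qg_dist=qg,
        residue_graph=res_graph,
        sequence_tokens=seq_emb.tokens,
        ligand_graph=lig_graph,
        hetero=hetero,
        hetero_protein_features=prot_feats,
        complex_id=complex_id,
    )


def _reindex(element: str, vocab) -> int:
    from .data_io import element_index

    return element_index(str(element), vocab)


def featurize_synthetic(
    cpx: SyntheticComplex, config: RunConfig, seed: int = 0, sequence_backend=None,
    complex_id: str = "",
) -> ComplexFeatures:
    lig_graph = featurize_ligand(cpx.ligand_mol, cpx.ligand_coords)
    return featurize_complex(
        cpx.protein, cpx.sequence, lig_graph, config, seed=seed,
        sequence_backend=sequence_backend, complex_id=complex_id,
    )


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------

class AffinityModel(Module):
    """The end-to-end trainable predictor."""

    def __init__(self, config: RunConfig, seq_width: int | None = None):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.fusion.d_model
        n_types = config.surface.atom_types

        self.surface_encoder = SurfaceEncoder(
            n_types, rng,
            chem_dim=config.surface.chem_dim,
            chem_hidden=config.surface.chem_hidden,
            out_dim=config.surface.embed_dim,
            n_layers=config.surface.n_layers,
            radius=config.surface.radius,
        )
        self.surface_adapter = Linear(config.surface.embed_dim, d, rng)

        self.structure_encoder = StructureEncoder(
            rng,
            hidden_scalar=config.structure.hidden_scalar,
            hidden_vector=config.structure.hidden_vector,
            n_layers=config.structure.n_layers,
            dropout=config.structure.dropout,
            dropout_seed=config.seed,
        )
        self.structure_adapter = Linear(config.structure.hidden_scalar, d, rng)

        if seq_width is None:
            seq_width = 1024 if config.sequence.backend == "protbert" else config.sequence.width
        self.sequence_adapter = Linear(seq_width, d, rng)

        self.fusion = FusionModule(
            d, config.fusion.n_heads, config.fusion.encoder_layers,
            config.fusion.decoder_layers, rng, share_decoders=config.fusion.share_decoders,
        )
        self.ligand_encoder = LigandEncoder(
            rng, hidden_dim=config.ligand.hidden_dim,
            atom_rounds=config.ligand.atom_rounds, mol_rounds=config.ligand.mol_rounds,
        )
        from .ligand import N_ATOM_FEATURES

        self.interaction_encoder = InteractionEncoder(
            N_ATOM_FEATURES, n_types, rng,
            hidden_dim=config.interaction.hidden_dim,
            out_dim=config.interaction.out_dim,
            n_rounds=config.interaction.n_rounds,
            pooling=config.interaction.pooling,
        )
        head_in = 3 * d + config.ligand.hidden_dim + config.interaction.out_dim
        self.head = MLP([head_in, config.train.head_hidden, config.train.head_hidden // 2, 1], rng)

    # ----------------------------------------------------------- modalities
    def modality_tokens(self, f: ComplexFeatures) -> dict[str, Tensor]:
        """Adapted (pre-fusion) token sets for each protein modality."""
        surface = self.surface_adapter(
            self.surface_encoder(f.chem_onehot, f.chem_inv_dist, f.curvatures, f.qg_dist)
        )
        structure = self.structure_adapter(self.structure_encoder(f.residue_graph))
        sequence = self.sequence_adapter(Tensor(f.sequence_tokens))
        return {"surface": surface, "structure": structure, "sequence": sequence}

    def protein_embedding(self, f: ComplexFeatures) -> tuple[Tensor, dict[str, Tensor], dict[str, Tensor]]:
        tokens = self.modality_tokens(f)
        fused, aligned = self.fusion(tokens["surface"], tokens["structure"], tokens["sequence"])
        return fused, tokens, aligned

    def __call__(self, f: ComplexFeatures) -> Tensor:
        fused, _, _ = self.protein_embedding(f)
        ligand = self.ligand_encoder(f.ligand_graph)
        inter = self.interaction_encoder(
            f.hetero, f.ligand_graph.atom_features, f.hetero_protein_features
        )
        return self.predict_from_embeddings(fused, ligand, inter)

    def predict_from_embeddings(self, fused: Tensor, ligand: Tensor, inter: Tensor) -> Tensor:
        for name, emb in (("protein", fused), ("ligand", ligand), ("interaction", inter)):
            if not np.all(np.isfinite(emb.data)):
                raise ValueError(f"non-finite {name} embedding")
        joint = concatenate([fused, ligand, inter], axis=-1)
        return self.head(joint.reshape(1, -1)).reshape(())

    def predict(self, f: ComplexFeatures) -> float:
        was_training = self.training
        self.eval()
        try:
            return float(self(f).data)
        finally:
            if was_training:
                self.train()

    # --------------------------------------------------------- persistence
    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        params = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path.with_suffix(".npz"), **params)
        path.with_suffix(".json").write_text(json.dumps(self.config.to_dict(), indent=1))

    def load_parameters(self, path) -> None:
        from pathlib import Path

        archive = np.load(Path(path).with_suffix(".npz"))
        params = self.parameters()
        if len(archive.files) != len(params):
            raise ValueError(
                f"checkpoint has {len(archive.files)} parameters, model expects {len(params)}"
            )
        for i, p in enumerate(params):
            data = archive[f"p{i}"]
            if data.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {data.shape} vs {p.data.shape}")
            p.data = data.astype(np.float64)


# --------------------------------------------------------------------------
# loss and metrics
# --------------------------------------------------------------------------

def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error 1/N sum (y_i - yhat_i)^2."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean((y - y_hat) ** 2))


def evaluate(records: list[AffinityRecord]) -> MetricsReport:
    """RMSE / MAE / SD / Pearson R over records carrying predictions."""
    if len(records) < 2:
        raise ValueError("need at least 2 records to evaluate")
    if any(r.y_hat is None for r in records):
        raise ValueError("all records must carry predictions")
    y = np.array([r.y for r in records])
    yh = np.array([r.y_hat for r in records])
    rmse = float(np.sqrt(np.mean((y - yh) ** 2)))
    mae = float(np.mean(np.abs(y - yh)))
    if np.std(yh) < 1e-12:
        warnings.warn("zero variance in predictions: R and SD undefined", stacklevel=2)
        r = sd = float("nan")
    else:
        from scipy import stats

        r = float(stats.pearsonr(y, yh).statistic)
        b, a = np.polyfit(yh, y, 1)
        resid = y - (a + b * yh)
        sd = float(np.sqrt(np.sum(resid**2) / (len(y) - 2))) if len(y) > 2 else 0.0
    return MetricsReport(rmse=rmse, mae=mae, sd=sd, r=r, n=len(records))


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def train(
    model: AffinityModel,
    train_set: list[tuple[ComplexFeatures, float]],
    val_set: list[tuple[ComplexFeatures, float]] | None = None,
    config=None,
) -> dict:
    """Seeded MSE/Adam training with early stopping on validation RMSE.

    Returns a history dict with per-epoch train loss (and val RMSE when a
    validation set is given); the model is left at the best-validation
    parameters (or the final parameters when no validation set exists).
    """
    cfg = config if config is not None else model.config.train
    if not train_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: dict = {"train_loss": [], "val_rmse": []}
    best_rmse, best_params, patience_left = np.inf, None, cfg.patience

    n = len(train_set)
    model.train()
    decay = getattr(cfg, "lr_decay", 1.0)
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr * decay**epoch
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start: start + cfg.batch_size]
            opt.zero_grad()
            loss = None
            for idx in batch:
                feats, y = train_set[idx]
                err = (model(feats) - float(y)) ** 2
                loss = err if loss is None else loss + err
            loss = loss / float(len(batch))
            if not np.isfinite(loss.data):
                logger.error("training diverged (non-finite loss) at epoch %d; stopping", epoch)
                if best_params is not None:
                    _restore(model, best_params)
                history["diverged"] = True
                return history
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(epoch_losses)))

        if val_set:
            preds = [model.predict(f) for f, _ in val_set]
            val_rmse = float(np.sqrt(np.mean((np.array([y for _, y in val_set]) - preds) ** 2)))
            history["val_rmse"].append(val_rmse)
            if val_rmse < best_rmse - 1e-9:
                best_rmse, best_params, patience_left = val_rmse, _snapshot(model), cfg.patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stopping at epoch %d (best val RMSE %.4f)", epoch, best_rmse)
                    break
    if val_set and best_params is not None:
        _restore(model, best_params)
    model.eval()
    return history


def _snapshot(model: Module) -> list[np.ndarray]:
    return [p.data.copy() for p in model.parameters()]


def _restore(model: Module, params: list[np.ndarray]) -> None:
    for p, saved in zip(model.parameters(), params):
        p.data = saved.copy()


# --------------------------------------------------------------------------
# alignment analysis
# --------------------------------------------------------------------------

def alignment_dispersion(
    model: AffinityModel, features: list[ComplexFeatures]
) -> tuple[float, float]:
    """Inter-modality centroid dispersion in 2D PCA space, before vs after alignment.

    Pools each modality's tokens per complex, projects the stacked
    (3 x n_complexes) embeddings to two principal components, and
    returns the mean pairwise distance between the three modality
    centroids — once for the pre-fusion tokens and once for the
    cross-attention-aligned tokens.
    """
    model.eval()
    before: dict[str, list[np.ndarray]] = {"surface": [], "structure": [], "sequence": []}
    after: dict[str, list[np.ndarray]] = {"surface": [], "structure": [], "sequence": []}
    for f in features:
        _, tokens, aligned = model.protein_embedding(f)
        for key in before:
            before[key].append(tokens[key].data.mean(axis=0))
            after[key].append(aligned[key].data.mean(axis=0))

    def dispersion(groups: dict[str, list[np.ndarray]]) -> float:
        keys = list(groups)
        X = np.vstack([np.vstack(groups[k]) for k in keys])
        proj = project_embeddings_2d(X)
        sizes = [len(groups[k]) for k in keys]
        bounds = np.cumsum([0] + sizes)
        centroids = [proj[a:b].mean(axis=0) for a, b in zip(bounds[:-1], bounds[1:])]
        dists = [
            np.linalg.norm(centroids[i] - centroids[j])
            for i in range(len(centroids))
            for j in range(i + 1, len(centroids))
        ]
        return float(np.mean(dists))

    return dispersion(before), dispersion(after)


# --------------------------------------------------------------------------
# feature bundle (de)serialization for the featurize/train workflow
# --------------------------------------------------------------------------

def features_to_arrays(f: ComplexFeatures) -> dict[str, np.ndarray]:
    g, lg, h = f.residue_graph, f.ligand_graph, f.hetero
    return {
        "chem_onehot": f.chem_onehot,
        "chem_inv_dist": f.chem_inv_dist,
        "curvatures": f.curvatures,
        "qg_dist": f.qg_dist,
        "rg_node_scalars": g.node_scalars,
        "rg_node_vectors": g.node_vectors,
        "rg_edge_index": g.edge_index,
        "rg_edge_scalars": g.edge_scalars,
        "rg_edge_vectors": g.edge_vectors,
        "rg_ca": g.ca_coords,
        "rg_res_ids": g.residue_ids,
        "sequence_tokens": f.sequence_tokens,
        "lg_atom_features": lg.atom_features,
        "lg_bond_index": lg.bond_index,
        "lg_bond_features": lg.bond_features,
        "lg_coords": lg.coords,
        "lg_elements": np.array(lg.elements, dtype="U4"),
        "h_lig": h.ligand_index,
        "h_prot": h.protein_index,
        "h_dist": h.distances,
        "h_sizes": np.array([h.n_ligand, h.n_protein]),
        "h_cutoff": np.array([h.cutoff]),
        "hetero_protein_features": f.hetero_protein_features,
        "complex_id": np.array([f.complex_id], dtype="U32"),
    }


def features_from_arrays(a) -> ComplexFeatures:
    graph = ResidueGraph(
        node_scalars=a["rg_node_scalars"],
        node_vectors=a["rg_node_vectors"],
        edge_index=a["rg_edge_index"],
        edge_scalars=a["rg_edge_scalars"],
        edge_vectors=a["rg_edge_vectors"],
        ca_coords=a["rg_ca"],
        residue_ids=a["rg_res_ids"],
    )
    lg = LigandGraph(
        atom_features=a["lg_atom_features"],
        bond_index=a["lg_bond_index"].astype(np.intp),
        bond_features=a["lg_bond_features"],
        coords=a["lg_coords"],
        elements=tuple(a["lg_elements"].tolist()),
    )
    h = HeteroGraph(
        ligand_index=a["h_lig"].astype(np.intp),
        protein_index=a["h_prot"].astype(np.intp),
        distances=a["h_dist"],
        n_ligand=int(a["h_sizes"][0]),
        n_protein=int(a["h_sizes"][1]),
        cutoff=float(a["h_cutoff"][0]),
    )
    return ComplexFeatures(
        chem_onehot=a["chem_onehot"],
        chem_inv_dist=a["chem_inv_dist"],
        curvatures=a["curvatures"],
        qg_dist=a["qg_dist"],
        residue_graph=graph,
        sequence_tokens=a["sequence_tokens"],
        ligand_graph=lg,
        hetero=h,
        hetero_protein_features=a["hetero_protein_features"],
        complex_id=str(a["complex_id"][0]),
    )
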