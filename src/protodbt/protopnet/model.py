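"""Prototypical-part classifier ("this looks like that") for lesion crops.

A convolutional backbone maps a grayscale crop to a latent grid; a prototype
layer holds m class-tagged latent vectors and, for each, computes an
activation map over the grid

    act(h, w) = log((d2 + 1) / (d2 + eps)),   d2 = ||z_hw - p_j||^2,

whose maximum is the prototype's similarity score; a final linear layer turns
the m scores into class logits.  Training minimizes

    CE + lambda_clst * cluster + lambda_sep * separation,

where the cluster term is the mean (over images) minimal squared distance
from any latent patch to a same-class prototype, and the separation term is
minus the corresponding minimal distance to other-class prototypes.  The
schedule is warm-up (backbone frozen) -> joint -> prototype projection onto
the nearest real training patch (which gives every prototype a provenance
record) -> last-layer-only optimization.  Low-purity prototypes can then be
pruned.  Explanations rank the top-k prototypes by similarity score and point
back to both the activated patch of the query image and the training patch
the prototype was projected onto.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .layers import Adam, Conv2d, MaxPool2, ReLU, Sequential, Sigmoid

__all__ = [
    "LossWeights",
    "TrainSchedule",
    "Prototype",
    "Explanation",
    "ProtoPNet",
]

CLASS_NAMES = ("benign", "cancer")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite loss; class_weights rebalance the
    cross-entropy (None => inverse class frequency)."""

    lambda_cluster: float = 0.8
    lambda_separation: float = 0.08
    class_weights: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.lambda_cluster < 0 or self.lambda_separation < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class TrainSchedule:
    n_warmup_epochs: int = 5
    n_joint_epochs: int = 10
    projection_interval: int = 0  # 0: project once, after the joint phase
    n_lastlayer_epochs: int = 10
    batch_size: int = 16
    lr: float = 2e-3
    lr_last_layer: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_warmup_epochs, self.n_joint_epochs,
               self.n_lastlayer_epochs, self.projection_interval) < 0:
            raise ValueError("schedule counts must be >= 0")


@dataclass
class Prototype:
    """A class-tagged latent vector; provenance is set by projection and
    points to the training patch the vector was snapped to."""

    class_id: int
    vector: np.ndarray  # (D,)
    provenance: dict | None = None  # {image_index, grid_hw, pixel_rect}


@dataclass
class Explanation:
    """Ranked prototype evidence supporting one classification."""

    predicted_class: str
    probabilities: dict[str, float]
    items: list[dict] = field(default_factory=list)
    # each item: prototype_index, prototype_class, similarity,
    #            image_rect (x, y, w, h), source (provenance dict)

    def to_json(self) -> str:
        return json.dumps({"predicted_class": self.predicted_class,
                           "probabilities": self.probabilities,
                           "items": self.items}, indent=2)


def _one_hot(y: np.ndarray, n: int = 2) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


class ProtoPNet:
    """Desk-scale prototypical-part network in NumPy.

    Parameters
    ----------
    in_size : input crop side in pixels (square crops).
    latent_dim : channels D of the latent grid.
    n_prototypes_per_class : prototypes allocated to each of the 2 classes.
    epsilon : similarity stabilizer in log((d2+1)/(d2+eps)).
    seed : initialization seed.
    """

    def __init__(self, in_size: int = 64, latent_dim: int = 24,
                 n_prototypes_per_class: int = 5, epsilon: float = 1e-4,
                 channels: tuple[int, ...] = (16, 32, 32), seed: int = 0):
        if in_size % (2 ** len(channels)) != 0:
            raise ValueError("in_size must be divisible by 2^n_blocks")
        if not 0 < epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        self.in_size = in_size
        self.latent_dim = latent_dim
        self.epsilon = epsilon
        self.seed = seed
        self.channels = tuple(channels)

        layers = []
        c_prev = 1
        for c in channels:
            layers += [Conv2d(c_prev, c, 3, rng), ReLU(), MaxPool2()]
            c_prev = c
        self.backbone = Sequential(*layers)
        # 1x1 add-on conv + sigmoid bounds the latent space in (0, 1)
        self.addon = Sequential(Conv2d(c_prev, latent_dim, 1, rng), Sigmoid())

        self.grid_size = in_size // (2 ** len(channels))
        m = 2 * n_prototypes_per_class
        self.prototypes = [
            Prototype(class_id=j // n_prototypes_per_class,
                      vector=rng.uniform(0.25, 0.75, size=latent_dim))
            for j in range(m)
        ]
        # last layer: +1 own-class, -0.5 cross-class
        self.W_last = np.where(
            np.arange(2)[:, None] == self.prototype_classes[None, :], 1.0, -0.5)
        self.history: list[dict] = []
        self._trained = False

    # ------------------------------------------------------------------ core

    @property
    def n_prototypes(self) -> int:
        return len(self.prototypes)

    @property
    def prototype_classes(self) -> np.ndarray:
        return np.array([p.class_id for p in self.prototypes])

    @property
    def prototype_matrix(self) -> np.ndarray:
        return np.stack([p.vector for p in self.prototypes])

    def _latent(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, S, S) float in [0,1] -> latent grid (N, D, Hz, Wz)."""
        return self.addon.forward(self.backbone.forward(x))

    def _distances(self, z: np.ndarray) -> np.ndarray:
        """Squared Euclidean distances (N, m, Hz, Wz) from latent patches to
        every prototype."""
        P = self.prototype_matrix  # (m, D)
        z2 = np.einsum("ndhw,ndhw->nhw", z, z)[:, None]
        p2 = np.einsum("md,md->m", P, P)[None, :, None, None]
        cross = np.einsum("ndhw,md->nmhw", z, P)
        return np.maximum(z2 + p2 - 2.0 * cross, 0.0)

    def activation_from_distances(self, d2: np.ndarray) -> np.ndarray:
        return np.log((d2 + 1.0) / (d2 + self.epsilon))

    def compute_activation_map(self, latent: np.ndarray,
                               prototype: Prototype) -> np.ndarray:
        """Activation map (Hz, Wz) of one prototype over one latent grid
        (D, Hz, Wz)."""
        if latent.shape[0] != prototype.vector.shape[0]:
            raise ValueError(
                f"latent depth {latent.shape[0]} != prototype dim "
                f"{prototype.vector.shape[0]}")
        diff = latent - prototype.vector[:, None, None]
        d2 = np.einsum("dhw,dhw->hw", diff, diff)
        return self.activation_from_distances(d2)

    def similarity_scores(self, latent: np.ndarray) -> np.ndarray:
        """Max-pooled similarity score of every prototype for one latent grid."""
        d2 = self._distances(latent[None])[0]
        return self.activation_from_distances(d2).max(axis=(1, 2))

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.shape[-1] != self.in_size or X.shape[-2] != self.in_size:
            raise ValueError(f"expected {self.in_size}x{self.in_size} crops, "
                             f"got {X.shape[-2]}x{X.shape[-1]}")
        return X.astype(np.float64).reshape(-1, 1, self.in_size, self.in_size) / 255.0

    def forward(self, X: np.ndarray) -> dict:
        """Inference pass: probabilities, similarity scores, activation maps."""
        x = self._prepare(X)
        z = self._latent(x)
        d2 = self._distances(z)
        act = self.activation_from_distances(d2)
        scores = act.max(axis=(2, 3))
        logits = scores @ self.W_last.T
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        return {"probabilities": probs, "scores": scores,
                "activation_maps": act, "distances": d2, "latent": z}

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)["probabilities"]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    # ------------------------------------------------------------------ loss

    def loss_terms(self, X: np.ndarray, y: np.ndarray,
                   weights: LossWeights) -> dict:
        """Composite loss on a batch (forward only; no gradients)."""
        out = self.forward(X)
        return self._loss_from_forward(out, np.asarray(y), weights)

    def _class_weight_vec(self, y: np.ndarray,
                          weights: LossWeights) -> np.ndarray:
        if weights.class_weights is not None:
            return np.asarray(weights.class_weights, dtype=float)
        counts = np.bincount(y, minlength=2).astype(float)
        counts[counts == 0] = 1.0
        cw = counts.sum() / (2.0 * counts)
        return cw

    def _loss_from_forward(self, out: dict, y: np.ndarray,
                           weights: LossWeights) -> dict:
        proto_cls = self.prototype_classes
        for c in (0, 1):
            if not np.any(proto_cls == c):
                raise ValueError(f"class {CLASS_NAMES[c]} has no prototype")
        probs, d2 = out["probabilities"], out["distances"]
        n = len(y)
        cw = self._class_weight_vec(y, weights)
        wvec = cw[y]
        nll = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
        ce = float((wvec * nll).sum() / wvec.sum())

        d2_min_patch = d2.min(axis=(2, 3))  # (N, m)
        same = proto_cls[None, :] == y[:, None]
        cluster = float(np.where(same, d2_min_patch, np.inf).min(axis=1).mean())
        sep_min = np.where(~same, d2_min_patch, np.inf).min(axis=1)
        separation = float(-sep_min.mean())
        total = (ce + weights.lambda_cluster * cluster
                 + weights.lambda_separation * separation)
        return {"total": total, "cross_entropy": ce, "cluster": cluster,
                "separation": separation}

    # -------------------------------------------------------------- training

    def _backward_batch(self, x: np.ndarray, y: np.ndarray,
                        weights: LossWeights,
                        train_protos: bool, train_last: bool,
                        train_features: bool) -> dict:
        """Forward + manual backward on one prepared batch; fills layer grads
        and returns loss terms plus dP/dW_last."""
        n = len(y)
        feats = self.backbone.forward(x)
        z = self.addon.forward(feats)
        d2 = self._distances(z)
        act = self.activation_from_distances(d2)
        m = self.n_prototypes

        act_flat = act.reshape(n, m, -1)
        amax = act_flat.argmax(axis=2)
        scores = act_flat.max(axis=2)
        logits = scores @ self.W_last.T
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        probs = e / e.sum(axis=1, keepdims=True)

        out = {"probabilities": probs, "distances": d2}
        terms = self._loss_from_forward(out, y, weights)

        cw = self._class_weight_vec(y, weights)
        wvec = cw[y]
        dlogits = (probs - _one_hot(y)) * (wvec / wvec.sum())[:, None]

        dW_last = dlogits.T @ scores if train_last else None

        dd2 = np.zeros_like(d2)
        if train_protos or train_features:
            # CE path: through max-pooled similarity scores
            dscores = dlogits @ self.W_last  # (N, m)
            dact_at_max = dscores  # gradient lands on the argmax cell
            # d act / d d2 at the argmax cells
            d2_flat = d2.reshape(n, m, -1)
            d2_at_max = np.take_along_axis(d2_flat, amax[:, :, None], axis=2)[..., 0]
            slope = 1.0 / (d2_at_max + 1.0) - 1.0 / (d2_at_max + self.epsilon)
            contrib = dact_at_max * slope
            dd2_flat = dd2.reshape(n, m, -1)
            np.put_along_axis(
                dd2_flat, amax[:, :, None],
                np.take_along_axis(dd2_flat, amax[:, :, None], axis=2)
                + contrib[:, :, None], axis=2)

            # cluster / separation paths: min over same-/other-class patches
            proto_cls = self.prototype_classes
            same = proto_cls[None, :] == y[:, None]
            big = np.inf
            d2_masked_same = np.where(same[:, :, None], d2_flat, big)
            idx_same = d2_masked_same.reshape(n, -1).argmin(axis=1)
            d2_masked_other = np.where(~same[:, :, None], d2_flat, big)
            idx_other = d2_masked_other.reshape(n, -1).argmin(axis=1)
            flat = dd2.reshape(n, -1)
            flat[np.arange(n), idx_same] += weights.lambda_cluster / n
            flat[np.arange(n), idx_other] -= weights.lambda_separation / n

        dP = None
        dz = None
        if train_protos or train_features:
            # d2[n,j,h,w] = ||z_nhw - p_j||^2
            P = self.prototype_matrix
            diff = z[:, None] - P[None, :, :, None, None]  # (N, m, D, Hz, Wz)
            g = dd2[:, :, None]  # broadcast over D
            dz = (2.0 * g * diff).sum(axis=1)  # (N, D, Hz, Wz)
            dP = (-2.0 * g * diff).sum(axis=(0, 3, 4))  # (m, D)

        if train_features and dz is not None:
            self.addon.zero_grad()
            self.backbone.zero_grad()
            dfeats = self.addon.backward(dz)
            self.backbone.backward(dfeats)
        elif train_protos and dz is not None:
            # warm-up trains the add-on convolution too (backbone frozen)
            self.addon.zero_grad()
            self.backbone.set_trainable(False)
            dfeats = self.addon.backward(dz)
            self.backbone.set_trainable(True)

        return {**terms, "dP": dP, "dW_last": dW_last}

    def _run_epochs(self, X: np.ndarray, y: np.ndarray, n_epochs: int,
                    phase: str, weights: LossWeights, schedule: TrainSchedule,
                    rng: np.random.Generator) -> None:
        if n_epochs == 0:
            return
        train_features = phase == "joint"
        train_protos = phase in ("warmup", "joint")
        train_last = phase == "last_layer"

        param_pairs: list[tuple[np.ndarray, np.ndarray]] = []
        self._P_param = self.prototype_matrix  # contiguous copy for the optimizer
        self._P_grad = np.zeros_like(self._P_param)
        self._W_grad = np.zeros_like(self.W_last)
        if train_protos:
            param_pairs.append((self._P_param, self._P_grad))
        if phase in ("warmup", "joint"):
            param_pairs += list(self.addon.params())
        if train_features:
            param_pairs += list(self.backbone.params())
        if train_last:
            param_pairs.append((self.W_last, self._W_grad))

        lr = schedule.lr_last_layer if train_last else schedule.lr
        opt = Adam(lr=lr)
        n = len(y)
        for _ in range(n_epochs):
            order = rng.permutation(n)
            epoch_terms = {"total": 0.0, "cross_entropy": 0.0,
                           "cluster": 0.0, "separation": 0.0}
            n_batches = 0
            for start in range(0, n, schedule.batch_size):
                idx = order[start:start + schedule.batch_size]
                xb = self._prepare(X[idx])
                yb = y[idx]
                self.addon.zero_grad()
                self.backbone.zero_grad()
                self._P_grad[...] = 0.0
                self._W_grad[...] = 0.0
                res = self._backward_batch(
                    xb, yb, weights, train_protos, train_last, train_features)
                if res["dP"] is not None and train_protos:
                    self._P_grad += res["dP"]
                if res["dW_last"] is not None and train_last:
                    self._W_grad += res["dW_last"]
                opt.step(param_pairs)
                if train_protos:
                    for j, p in enumerate(self.prototypes):
                        p.vector = self._P_param[j].copy()
                for k in epoch_terms:
                    epoch_terms[k] += res[k]
                n_batches += 1
            self.history.append(
                {"phase": phase,
                 **{k: v / max(1, n_batches) for k, v in epoch_terms.items()}})

    def fit(self, X: np.ndarray, y: np.ndarray,
            schedule: TrainSchedule = TrainSchedule(),
            weights: LossWeights = LossWeights(),
            image_ids: list[str] | None = None) -> "ProtoPNet":
        """Four-phase training: warm-up, joint, projection, last layer.

        `history` gains one record per epoch with the phase label and the
        averaged loss terms.
        """
        y = np.asarray(y, dtype=int)
        if len(np.bincount(y, minlength=2).nonzero()[0]) < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(schedule.seed)
        self._run_epochs(X, y, schedule.n_warmup_epochs, "warmup",
                         weights, schedule, rng)
        if schedule.projection_interval > 0:
            done = 0
            while done < schedule.n_joint_epochs:
                chunk = min(schedule.projection_interval,
                            schedule.n_joint_epochs - done)
                self._run_epochs(X, y, chunk, "joint", weights, schedule, rng)
                self.project_prototypes(X, y, image_ids)
                done += chunk
        else:
            self._run_epochs(X, y, schedule.n_joint_epochs, "joint",
                             weights, schedule, rng)
            self.project_prototypes(X, y, image_ids)
        self._run_epochs(X, y, schedule.n_lastlayer_epochs, "last_layer",
                         weights, schedule, rng)
        self._trained = True
        return self

    # ------------------------------------------------- projection and pruning

    def _all_patches(self, X: np.ndarray, batch: int = 64
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Latent patches of a crop set: (patches (K, D), image_index (K,),
        grid position (K, 2))."""
        ps, ims, pos = [], [], []
        hz = self.grid_size
        for start in range(0, len(X), batch):
            xb = self._prepare(X[start:start + batch])
            z = self._latent(xb)  # (n, D, Hz, Wz)
            n = z.shape[0]
            zt = z.transpose(0, 2, 3, 1).reshape(-1, self.latent_dim)
            ps.append(zt)
            grid = np.indices((hz, hz)).reshape(2, -1).T
            for i in range(n):
                ims.append(np.full(hz * hz, start + i))
                pos.append(grid)
        return np.concatenate(ps), np.concatenate(ims), np.concatenate(pos)

    def grid_to_pixel_rect(self, h: int, w: int) -> tuple[int, int, int, int]:
        """Input-pixel rectangle (x, y, w, h) corresponding to a latent cell."""
        cell = self.in_size // self.grid_size
        return (w * cell, h * cell, cell, cell)

    def project_prototypes(self, X: np.ndarray, y: np.ndarray,
                           image_ids: list[str] | None = None) -> "ProtoPNet":
        """Snap every prototype to its nearest same-class training patch and
        record provenance.  Idempotent."""
        y = np.asarray(y, dtype=int)
        patches, im_idx, pos = self._all_patches(X)
        patch_labels = y[im_idx]
        for p in self.prototypes:
            mask = patch_labels == p.class_id
            cand = patches[mask]
            if len(cand) == 0:
                raise ValueError(f"no training patches of class {p.class_id}")
            d2 = ((cand - p.vector) ** 2).sum(axis=1)
            k = int(d2.argmin())
            sel = np.nonzero(mask)[0][k]
            h, w = (int(v) for v in pos[sel])
            img = int(im_idx[sel])
            p.vector = patches[sel].copy()
            # lists, not tuples: provenance must survive a JSON round trip
            p.provenance = {
                "image_index": img,
                "image_id": image_ids[img] if image_ids else str(img),
                "grid_hw": [h, w],
                "pixel_rect": list(self.grid_to_pixel_rect(h, w)),
            }
        return self

    def prune_prototypes(self, X: np.ndarray, y: np.ndarray,
                         k_nearest: int = 6, purity_threshold: float = 0.5,
                         schedule: TrainSchedule | None = None,
                         weights: LossWeights = LossWeights()) -> "ProtoPNet":
        """Drop prototypes whose k-nearest training patches are mostly of the
        wrong class; always keep the highest-purity prototype of each class;
        then re-optimize the last layer."""
        y = np.asarray(y, dtype=int)
        patches, im_idx, _pos = self._all_patches(X)
        patch_labels = y[im_idx]
        purities = []
        for p in self.prototypes:
            d2 = ((patches - p.vector) ** 2).sum(axis=1)
            nearest = np.argsort(d2, kind="stable")[:k_nearest]
            purities.append(float((patch_labels[nearest] == p.class_id).mean()))
        keep = [i for i, pur in enumerate(purities) if pur >= purity_threshold]
        for c in (0, 1):
            if not any(self.prototypes[i].class_id == c for i in keep):
                cls_idx = [i for i, p in enumerate(self.prototypes)
                           if p.class_id == c]
                best = max(cls_idx, key=lambda i: purities[i])
                keep.append(best)
        keep = sorted(set(keep))
        self.prototypes = [self.prototypes[i] for i in keep]
        self.W_last = self.W_last[:, keep]
        if schedule is not None and schedule.n_lastlayer_epochs > 0:
            rng = np.random.default_rng(schedule.seed + 1)
            self._run_epochs(X, y, schedule.n_lastlayer_epochs, "last_layer",
                             weights, schedule, rng)
        return self

    # ---------------------------------------------------------- explanations

    def explain(self, image: np.ndarray, k: int = 5,
                scope: str = "predicted") -> Explanation:
        """Top-k prototype evidence for one crop's classification.

        With the default scope "predicted" the ranking runs over the
        predicted class's prototypes — the case-based-reasoning presentation
        ("cancer, because these patches look like these cancer prototypes").
        scope="all" ranks every prototype regardless of class.
        """
        if any(p.provenance is None for p in self.prototypes):
            raise RuntimeError("prototypes must be projected before explaining")
        out = self.forward(image)
        probs = out["probabilities"][0]
        scores = out["scores"][0]
        act = out["activation_maps"][0]  # (m, Hz, Wz)
        pred = int(probs.argmax())
        if scope == "predicted":
            pool = np.nonzero(self.prototype_classes == pred)[0]
        elif scope == "all":
            pool = np.arange(self.n_prototypes)
        else:
            raise ValueError("scope must be 'predicted' or 'all'")
        if k > len(pool):
            import warnings
            warnings.warn(f"k={k} exceeds the {len(pool)} available "
                          "prototypes; clipping")
            k = len(pool)
        order = pool[np.argsort(-scores[pool], kind="stable")[:k]]
        items = []
        for j in order:
            h, w = np.unravel_index(act[j].argmax(), act[j].shape)
            items.append({
                "prototype_index": int(j),
                "prototype_class": CLASS_NAMES[self.prototypes[j].class_id],
                "similarity": float(scores[j]),
                "image_rect": self.grid_to_pixel_rect(int(h), int(w)),
                "source": self.prototypes[j].provenance,
            })
        return Explanation(
            predicted_class=CLASS_NAMES[pred],
            probabilities={CLASS_NAMES[i]: float(probs[i]) for i in (0, 1)},
            items=items)

    def render_explanation(self, image: np.ndarray, explanation: Explanation,
                           train_images: np.ndarray, out_path: str | Path) -> Path:
        """Side-by-side overlay figure: query patch vs. each prototype's
        source training patch."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import matplotlib.patches as mpatches

        k = len(explanation.items)
        fig, axes = plt.subplots(k, 2, figsize=(5, 2.4 * k), squeeze=False)
        for row, item in enumerate(explanation.items):
            ax_q, ax_p = axes[row]
            ax_q.imshow(image, cmap="gray")
            x, y, w, h = item["image_rect"]
            ax_q.add_patch(mpatches.Rectangle((x, y), w, h, fill=False,
                                              edgecolor="yellow", lw=2))
            ax_q.set_title(f"query (sim {item['similarity']:.2f})", fontsize=8)
            src = item["source"]
            ax_p.imshow(train_images[src["image_index"]], cmap="gray")
            x, y, w, h = src["pixel_rect"]
            ax_p.add_patch(mpatches.Rectangle((x, y), w, h, fill=False,
                                              edgecolor="yellow", lw=2))
            ax_p.set_title(f"prototype [{item['prototype_class']}]", fontsize=8)
            for ax in (ax_q, ax_p):
                ax.axis("off")
        fig.suptitle(f"predicted: {explanation.predicted_class}")
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(out_path, dpi=110, bbox_inches="tight")
        plt.close(fig)
        return out_path

    # ------------------------------------------------------------ checkpoint

    def save(self, path: str | Path) -> Path:
        """Single-archive checkpoint: parameters, prototypes + provenance,
        last layer, config snapshot."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {"W_last": self.W_last}
        for i, layer in enumerate(self.backbone.layers):
            if isinstance(layer, Conv2d):
                arrays[f"backbone_{i}_W"] = layer.W
                arrays[f"backbone_{i}_b"] = layer.b
        arrays["addon_W"] = self.addon.layers[0].W
        arrays["addon_b"] = self.addon.layers[0].b
        arrays["prototypes"] = self.prototype_matrix
        arrays["prototype_classes"] = self.prototype_classes
        config = {
            "in_size": self.in_size, "latent_dim": self.latent_dim,
            "epsilon": self.epsilon, "channels": list(self.channels),
            "seed": self.seed,
            "provenance": [p.provenance for p in self.prototypes],
            "history": self.history, "trained": self._trained,
        }
        np.savez(path, **arrays, config=json.dumps(config))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ProtoPNet":
        with np.load(path, allow_pickle=False) as data:
            config = json.loads(str(data["config"]))
            proto_vecs = data["prototypes"]
            proto_cls = data["prototype_classes"]
            model = cls(in_size=config["in_size"],
                        latent_dim=config["latent_dim"],
                        n_prototypes_per_class=1,
                        epsilon=config["epsilon"],
                        channels=tuple(config["channels"]),
                        seed=config["seed"])
            model.prototypes = [
                Prototype(class_id=int(c), vector=v.copy(),
                          provenance=config["provenance"][i])
                for i, (c, v) in enumerate(zip(proto_cls, proto_vecs))]
            model.W_last = data["W_last"].copy()
            for i, layer in enumerate(model.backbone.layers):
                if isinstance(layer, Conv2d):
                    layer.W = data[f"backbone_{i}_W"].copy()
                    layer.b = data[f"backbone_{i}_b"].copy()
                    layer.dW = np.zeros_like(layer.W)
                    layer.db = np.zeros_like(layer.b)
            model.addon.layers[0].W = data["addon_W"].copy()
            model.addon.layers[0].b = data["addon_b"].copy()
            model.addon.layers[0].dW = np.zeros_like(model.addon.layers[0].W)
            model.addon.layers[0].db = np.zeros_like(model.addon.layers[0].b)
            model.history = config["history"]
            model._trained = config["trained"]
        return model
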