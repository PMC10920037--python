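"""Recurrent variational deep embedding for masked multivariate trajectories.

The model is a variational autoencoder whose latent prior is a K-component
diagonal Gaussian mixture, so posterior component responsibilities yield a
clustering.  Sequences are encoded by a single-layer LSTM; unobserved
entries are replaced at the input by learned per-(wave, assessment)
imputation values and excluded from the reconstruction loss, so imputation,
representation learning and clustering are fit jointly.

Training proceeds in three stages: reconstruction-only pretraining of the
autoencoder and imputation values, EM initialization of the mixture on the
encoded latent means, and joint gradient training of the full objective
(masked mean squared reconstruction error plus the mixture KL latent loss).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp as np_logsumexp
from sklearn.mixture import GaussianMixture

from . import _autodiff as ad
from ._autodiff import Tensor
from ._util import spawn_seed
from .preprocessing import TrajectoryTensor

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VaderConfig:
    k: int = 5
    latent_dim: int = 8
    hidden_size: int = 32
    epochs: int = 100
    pretrain_epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 1e-3
    # joint fine-tuning uses a gentler rate: with an aggressive step size the
    # responsibility-weighted latent loss tends to empty small mixture
    # components soon after EM initialization
    finetune_learning_rate: float = 5e-4
    variance_floor: float = 1e-4
    grad_clip: float = 5.0
    em_restarts: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.latent_dim < 1:
            raise ValueError("k and latent_dim must be >= 1")
        if self.epochs < 0 or self.pretrain_epochs < 0:
            raise ValueError("epoch counts must be >= 0")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # (N,) int, argmax responsibilities (ties -> lowest index)
    responsibilities: np.ndarray  # (N, K), rows sum to 1


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params: list[Tensor], lr: float, clip: float = 5.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.clip, self.eps = lr, clip, eps
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        norm = float(np.sqrt(sum((g**2).sum() for g in grads)))
        if self.clip and norm > self.clip:
            grads = [g * (self.clip / norm) for g in grads]
        self.t += 1
        for i, (p, g) in enumerate(zip(self.params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class VaderModel:
    """Parameters of the recurrent mixture VAE.

    Network parameters live as autodiff tensors; the mixture prior is kept
    as a softmax-parameterized weight vector and per-component means and
    log-variances (variances floored at ``config.variance_floor``).
    """

    _GATES = ("i", "f", "o", "g")

    def __init__(self, config: VaderConfig, n_timesteps: int, n_features: int):
        self.config = config
        self.T, self.D = n_timesteps, n_features
        H, L, K = config.hidden_size, config.latent_dim, config.k
        rng = np.random.default_rng(config.seed)

        def init(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        p: dict[str, Tensor] = {}
        for gate in self._GATES:
            p[f"enc_Wx_{gate}"] = init(self.D, H)
            p[f"enc_Wh_{gate}"] = init(H, H)
            p[f"enc_b_{gate}"] = Tensor(np.zeros((1, H)), requires_grad=True)
        p["enc_b_f"].data += 1.0  # forget-gate bias init
        p["W_mu"], p["b_mu"] = init(H, L), Tensor(np.zeros((1, L)), requires_grad=True)
        p["W_lv"], p["b_lv"] = init(H, L), Tensor(np.full((1, L), -1.0), requires_grad=True)
        p["dec_Wzh"], p["dec_bzh"] = init(L, H), Tensor(np.zeros((1, H)), requires_grad=True)
        p["dec_Wzc"], p["dec_bzc"] = init(L, H), Tensor(np.zeros((1, H)), requires_grad=True)
        for gate in self._GATES:
            p[f"dec_Wh_{gate}"] = init(H, H)
            p[f"dec_b_{gate}"] = Tensor(np.zeros((1, H)), requires_grad=True)
        p["dec_b_f"].data += 1.0
        p["W_out"], p["b_out"] = init(H, self.D), Tensor(np.zeros((1, self.D)), requires_grad=True)
        # learned imputation values, one scalar per (wave, assessment) cell
        for t in range(self.T):
            p[f"B_{t}"] = Tensor(np.zeros((1, self.D)), requires_grad=True)
        # mixture prior
        p["pi_logits"] = Tensor(np.zeros(K), requires_grad=True)
        p["mix_mu"] = Tensor(rng.normal(0.0, 0.1, size=(K, L)), requires_grad=True)
        p["mix_lv"] = Tensor(np.zeros((K, L)), requires_grad=True)
        self.params = p

    # -- parameter groups --------------------------------------------------

    def network_params(self) -> list[Tensor]:
        return [v for k, v in self.params.items()
                if not k.startswith(("pi_", "mix_"))]

    def all_params(self) -> list[Tensor]:
        return list(self.params.values())

    # -- numpy views of the mixture ---------------------------------------

    @property
    def mixture_weights(self) -> np.ndarray:
        logits = self.params["pi_logits"].data
        w = np.exp(logits - logits.max())
        return w / w.sum()

    @property
    def mixture_means(self) -> np.ndarray:
        return self.params["mix_mu"].data.copy()

    @property
    def mixture_variances(self) -> np.ndarray:
        return np.exp(self.params["mix_lv"].data) + self.config.variance_floor

    # -- graph-building forward passes -------------------------------------

    def _impute_inputs(self, values: np.ndarray, mask: np.ndarray) -> list[Tensor]:
        """x̃_t = mask ⊙ x + (1 − mask) ⊙ B, one tensor per timestep."""
        xs = []
        for t in range(self.T):
            m = mask[:, t, :]
            x = np.where(m > 0, np.nan_to_num(values[:, t, :]), 0.0)
            xs.append(Tensor(m * x) + Tensor(1.0 - m) * self.params[f"B_{t}"])
        return xs

    def _lstm(self, xs: list[Tensor] | None, prefix: str, h: Tensor, c: Tensor,
              steps: int) -> list[Tensor]:
        p = self.params
        hs = []
        for t in range(steps):
            def gate(name, act):
                pre = h @ p[f"{prefix}_Wh_{name}"] + p[f"{prefix}_b_{name}"]
                if xs is not None:
                    pre = pre + xs[t] @ p[f"{prefix}_Wx_{name}"]
                return act(pre)

            i = gate("i", ad.sigmoid)
            f = gate("f", ad.sigmoid)
            o = gate("o", ad.sigmoid)
            g = gate("g", ad.tanh)
            c = f * c + i * g
            h = o * ad.tanh(c)
            hs.append(h)
        return hs

    def encode(self, values: np.ndarray, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Masked sequence -> (μ̃, log σ̃²), both (N, L)."""
        n = values.shape[0]
        H = self.config.hidden_size
        xs = self._impute_inputs(values, mask)
        h0 = Tensor(np.zeros((n, H)))
        c0 = Tensor(np.zeros((n, H)))
        h = self._lstm(xs, "enc", h0, c0, self.T)[-1]
        mu = h @ self.params["W_mu"] + self.params["b_mu"]
        logvar = h @ self.params["W_lv"] + self.params["b_lv"]
        return mu, logvar

    def decode(self, z: Tensor) -> list[Tensor]:
        """Latent -> reconstructed sequence, one (N, D) tensor per timestep."""
        p = self.params
        h = ad.tanh(z @ p["dec_Wzh"] + p["dec_bzh"])
        c = ad.tanh(z @ p["dec_Wzc"] + p["dec_bzc"])
        hs = self._lstm(None, "dec", h, c, self.T)
        return [h_t @ p["W_out"] + p["b_out"] for h_t in hs]

    def encode_numpy(self, data: TrajectoryTensor) -> np.ndarray:
        """Deterministic latent means μ̃ as a plain array (no graph kept)."""
        mu, _ = self.encode(data.values, data.mask)
        return mu.data.copy()

    # -- persistence --------------------------------------------------------

    def save(self, path):
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"),
                            **{k: v.data for k, v in self.params.items()})
        meta = {"config": asdict(self.config), "T": self.T, "D": self.D}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "VaderModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(VaderConfig(**meta["config"]), meta["T"], meta["D"])
        arrays = np.load(path.with_suffix(".npz"))
        for k in model.params:
            model.params[k].data = arrays[k].copy()
        return model


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def _mixture_log_joint(model: VaderModel, z: Tensor) -> Tensor:
    """log π_c + log N(z; μ_c, diag σ²_c) for every component, (N, K)."""
    K, L = model.config.k, model.config.latent_dim
    p = model.params
    log_pi = p["pi_logits"] - ad.logsumexp(p["pi_logits"], axis=0, keepdims=True)
    sigma2 = ad.exp(p["mix_lv"]) + model.config.variance_floor  # (K, L)
    n = z.shape[0]
    diff = z.reshape(n, 1, L) - p["mix_mu"].reshape(1, K, L)
    log_norm = (Tensor(-0.5 * LOG2PI * L)
                - 0.5 * ad.log(sigma2).sum(axis=1).reshape(1, K)
                - 0.5 * (diff**2 / sigma2.reshape(1, K, L)).sum(axis=2))
    return log_pi.reshape(1, K) + log_norm


def loss_terms(model: VaderModel, values: np.ndarray, mask: np.ndarray,
               eps: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """Masked reconstruction loss and mixture latent loss for one batch.

    ``reconstruction`` is the mean squared error over observed cells only;
    unobserved inputs are filled with the learned imputation values before
    encoding.  ``latent`` is the responsibility-weighted sum of closed-form
    diagonal-Gaussian KL divergences to each mixture component plus the
    responsibilities' KL to the mixture weights, averaged over the batch.
    Responsibilities are evaluated at the reparameterized sample
    z = μ̃ + σ̃ ⊙ ε when ``eps`` is given and at μ̃ otherwise.
    """
    if mask.sum() == 0:
        raise ValueError("all cells masked: nothing to reconstruct")
    n = values.shape[0]
    K, L = model.config.k, model.config.latent_dim

    mu, logvar = model.encode(values, mask)
    if eps is not None:
        z = mu + ad.exp(0.5 * logvar) * Tensor(eps)
    else:
        z = mu

    xhat = model.decode(z)
    sq = None
    for t in range(model.T):
        m = mask[:, t, :]
        x = np.where(m > 0, np.nan_to_num(values[:, t, :]), 0.0)
        term = (Tensor(m) * (Tensor(x) - xhat[t]) ** 2).sum()
        sq = term if sq is None else sq + term
    reconstruction = sq * (1.0 / float(mask.sum()))

    log_joint = _mixture_log_joint(model, z)  # (N, K)
    log_gamma = log_joint - ad.logsumexp(log_joint, axis=1, keepdims=True)
    gamma = ad.exp(log_gamma)

    sigma2_c = ad.exp(model.params["mix_lv"]) + model.config.variance_floor
    log_sigma2_c = ad.log(sigma2_c)
    # KL(N(μ̃, σ̃²) || N(μ_c, σ²_c)) per component, closed form, (N, K)
    mu_e = mu.reshape(n, 1, L)
    lv_e = logvar.reshape(n, 1, L)
    kl = 0.5 * ((log_sigma2_c.reshape(1, K, L) - lv_e
                 + (ad.exp(lv_e) + (mu_e - model.params["mix_mu"].reshape(1, K, L)) ** 2)
                 / sigma2_c.reshape(1, K, L)) - 1.0).sum(axis=2)
    log_pi = (model.params["pi_logits"]
              - ad.logsumexp(model.params["pi_logits"], axis=0, keepdims=True))
    entropy_term = (gamma * (log_gamma - log_pi.reshape(1, K))).sum(axis=1)
    latent = ((gamma * kl).sum(axis=1) + entropy_term).mean()
    return reconstruction, latent


# ---------------------------------------------------------------------------
# training stages
# ---------------------------------------------------------------------------


def _init_imputation_values(model: VaderModel, data: TrajectoryTensor):
    """Start the learned imputation values at per-(wave, assessment) means."""
    with np.errstate(invalid="ignore"):
        sums = np.where(data.mask > 0, np.nan_to_num(data.values), 0.0).sum(axis=0)
        counts = data.mask.sum(axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    for t in range(model.T):
        model.params[f"B_{t}"].data = means[t][None, :].copy()


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def pretrain(data: TrajectoryTensor, config: VaderConfig,
             model: VaderModel | None = None) -> tuple[VaderModel, list[dict]]:
    """Autoencoder + imputation training on reconstruction loss only."""
    if model is None:
        model = VaderModel(config, data.values.shape[1], data.values.shape[2])
    _init_imputation_values(model, data)
    log: list[dict] = []
    if config.pretrain_epochs == 0:
        return model, log
    rng = np.random.default_rng(spawn_seed(config.seed, 1))
    opt = Adam(model.network_params(), config.learning_rate, config.grad_clip)
    for epoch in range(config.pretrain_epochs):
        losses = []
        for idx in _batches(data.n, config.batch_size, rng):
            opt.zero_grad()
            recon, _latent = loss_terms(model, data.values[idx], data.mask[idx], eps=None)
            recon.backward()
            opt.step()
            losses.append(float(recon.data))
        log.append({"stage": "pretrain", "epoch": epoch, "reconstruction": float(np.mean(losses))})
    return model, log


def init_mixture(model: VaderModel, data: TrajectoryTensor, k: int | None = None) -> VaderModel:
    """EM fit of a diagonal Gaussian mixture on the encoded latent means."""
    k = k if k is not None else model.config.k
    if k > data.n:
        raise ValueError(f"k={k} exceeds the {data.n} participants")
    latents = model.encode_numpy(data)
    gm = GaussianMixture(n_components=k, covariance_type="diag",
                         n_init=model.config.em_restarts, init_params="k-means++",
                         reg_covar=model.config.variance_floor,
                         random_state=spawn_seed(model.config.seed, 2))
    gm.fit(latents)
    model.params["pi_logits"].data = np.log(np.maximum(gm.weights_, 1e-12))
    model.params["mix_mu"].data = gm.means_.copy()
    var = np.maximum(gm.covariances_ - model.config.variance_floor,
                     model.config.variance_floor)
    model.params["mix_lv"].data = np.log(var)
    return model


def train_full(model: VaderModel, data: TrajectoryTensor,
               config: VaderConfig | None = None) -> tuple[VaderModel, list[dict]]:
    """Joint stochastic-gradient training of the full objective."""
    config = config or model.config
    log: list[dict] = []
    if config.epochs == 0:
        return model, log
    rng = np.random.default_rng(spawn_seed(config.seed, 3))
    opt = Adam(model.all_params(), config.finetune_learning_rate, config.grad_clip)
    L = config.latent_dim
    for epoch in range(config.epochs):
        recs, lats = [], []
        for idx in _batches(data.n, config.batch_size, rng):
            opt.zero_grad()
            eps = rng.standard_normal((len(idx), L))
            recon, latent = loss_terms(model, data.values[idx], data.mask[idx], eps=eps)
            # ELBO scaling: the Gaussian likelihood sums squared error over a
            # participant's observed cells, while `recon` reports the masked
            # mean; reweight so the data term is a per-participant sum.
            cells_per_participant = float(data.mask[idx].sum()) / len(idx)
            total = recon * cells_per_participant + latent
            if not np.isfinite(total.data):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            total.backward()
            opt.step()
            recs.append(float(recon.data))
            lats.append(float(latent.data))
        log.append({"stage": "train", "epoch": epoch,
                    "reconstruction": float(np.mean(recs)), "latent": float(np.mean(lats))})
    return model, log


def fit(data: TrajectoryTensor, config: VaderConfig) -> tuple[VaderModel, list[dict]]:
    """Pretrain, initialize the mixture, then train the joint objective."""
    model, log1 = pretrain(data, config)
    init_mixture(model, data)
    model, log2 = train_full(model, data)
    return model, log1 + log2


def assign(model: VaderModel, data: TrajectoryTensor) -> ClusterAssignment:
    """Posterior responsibilities at z = μ̃ (no sampling) and argmax labels."""
    if data.values.shape[1] != model.T or data.values.shape[2] != model.D:
        raise ValueError("data dimensions do not match the model")
    z = model.encode_numpy(data)
    log_pi = np.log(model.mixture_weights)
    var = model.mixture_variances
    mu = model.mixture_means
    diff = z[:, None, :] - mu[None, :, :]
    log_joint = (log_pi[None, :]
                 - 0.5 * (LOG2PI * model.config.latent_dim + np.log(var).sum(axis=1))[None, :]
                 - 0.5 * (diff**2 / var[None, :, :]).sum(axis=2))
    gamma = np.exp(log_joint - np_logsumexp(log_joint, axis=1, keepdims=True))
    return ClusterAssignment(labels=gamma.argmax(axis=1), responsibilities=gamma)
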