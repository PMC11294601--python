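"""Dual-task cycle-GAN core: networks, losses, coupled objective, training.

Two cycle-GAN tasks share no weights but are coupled through their loss
functions. Task 1 translates raw images (domain A) into binary membrane maps
(domain B); task 2 translates ridge-enhanced images (domain C) into the same
binary domain. Each task has two generators and two discriminators, eight
networks in total:

====  ==========================  ====================================
name  role                        adversary
====  ==========================  ====================================
GA2B  raw -> binary               DB1 (binary real/fake, task 1)
GB2A  binary -> raw               DA  (raw real/fake)
GC2B  enhanced -> binary          DB2 (binary real/fake, task 2)
GB2C  binary -> enhanced          DC  (enhanced real/fake)
====  ==========================  ====================================

The binary-producing generators GA2B and GC2B are updated on the *shared*
loss: the maximum of the two per-task weighted loss totals. Taking the
subgradient of the max means only the currently-worse task receives gradient
on a given step, which synchronises training across the two tasks. The
reverse generators GB2A/GB2C keep their own task losses.

Per-task loss trio for the binary direction (weights 1 / lambda_identity /
lambda_cycle):

* adversarial: MSE of the discriminator score grid against 1,
* identity:    MAE between G(b) and b for a real binary image b,
* cycle:       MAE between G(G_rev(b)) and b (round-trip reconstruction).

The cycle term is weighted 10x the adversarial term by default.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn

GENERATOR_NAMES = ("GA2B", "GB2A", "GC2B", "GB2C")
DISCRIMINATOR_NAMES = ("DB1", "DA", "DB2", "DC")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class GanConfig:
    """Training configuration.

    ``ni``/``no`` are the dataset sizes used by the ``paper_global`` Xavier
    bound (862 input images, 400 binary output images); ``xavier_mode``
    selects between that global truncated normal and the conventional
    per-layer Glorot normal. ``ema_decay_beta1`` is Adam's first-moment decay
    rate; a value of 1 (selectable) freezes the moving average.
    """

    image_size: int = 256
    learning_rate: float = 0.002
    ema_decay_beta1: float = 0.5
    adam_beta2: float = 0.999
    lambda_cycle: float = 10.0
    lambda_identity: float = 5.0
    epochs: int = 200
    checkpoint_interval: int = 400
    n_res_blocks: int = 6
    ngf: int = 32
    ndf: int = 32
    batch_size: int = 1
    rng_seed: int = 0
    xavier_mode: str = "per_layer"  # per_layer | paper_global
    ni: int = 862
    no: int = 400
    disc_label_convention: str = "standard"  # standard | as_printed

    def __post_init__(self):
        if self.image_size % 4 != 0:
            raise ValueError("image_size must be a multiple of 4")
        if self.checkpoint_interval < 1:
            raise ValueError("checkpoint_interval must be >= 1")
        if self.xavier_mode not in ("per_layer", "paper_global"):
            raise ValueError(f"unknown xavier_mode {self.xavier_mode!r}")
        if self.disc_label_convention not in ("standard", "as_printed"):
            raise ValueError(f"unknown disc_label_convention {self.disc_label_convention!r}")


def desk_config(**overrides) -> GanConfig:
    """Desk-scale recipe: small images and narrow nets for single-CPU runs."""
    base = dict(
        image_size=64, ngf=8, ndf=8, n_res_blocks=2, batch_size=4,
        epochs=200, checkpoint_interval=50,
    )
    base.update(overrides)
    return GanConfig(**base)


@dataclass
class NetworkSet:
    generators: dict
    discriminators: dict
    optimizers: dict
    cfg: GanConfig

    def __post_init__(self):
        n = len(self.generators) + len(self.discriminators)
        if n != 8:
            raise ValueError(f"expected 8 networks, got {n}")

    def __getitem__(self, name):
        if name in self.generators:
            return self.generators[name]
        return self.discriminators[name]

    def state_dict(self):
        return {name: self[name].state_dict()
                for name in GENERATOR_NAMES + DISCRIMINATOR_NAMES}

    def load_state_dict(self, state):
        for name in GENERATOR_NAMES + DISCRIMINATOR_NAMES:
            self[name].load_state_dict(state[name])


@dataclass
class LossBundle:
    """Per-task loss components and the shared (max) coupled loss."""

    adv_1: float
    id_1: float
    cyc_1: float
    adv_2: float
    id_2: float
    cyc_2: float
    total_1: float
    total_2: float
    shared: float

    @property
    def argmax_task(self) -> int:
        return 1 if self.total_1 >= self.total_2 else 2


@dataclass
class Checkpoint:
    epoch: int
    state: dict
    cfg: GanConfig

    def save(self, path):
        flat = {"epoch": np.array(self.epoch)}
        for net, sd in self.state.items():
            for k, v in sd.items():
                flat[f"{net}/{k}"] = v
        np.savez_compressed(path, **flat)
        cfg_path = Path(path).with_suffix(".cfg.json")
        import json

        cfg_path.write_text(json.dumps(dataclasses.asdict(self.cfg)))


def load_checkpoint(path) -> Checkpoint:
    import json

    data = np.load(path)
    state: dict = {}
    epoch = 0
    for key in data.files:
        if key == "epoch":
            epoch = int(data[key])
            continue
        net, pname = key.split("/", 1)
        state.setdefault(net, {})[pname] = data[key]
    cfg = GanConfig(**json.loads(Path(path).with_suffix(".cfg.json").read_text()))
    return Checkpoint(epoch=epoch, state=state, cfg=cfg)


# ---------------------------------------------------------------------------
# Network construction


def build_generator(cfg: GanConfig) -> nn.Sequential:
    g = cfg.ngf
    return nn.Sequential(
        nn.Conv2d(1, g, 7, pad=3), nn.InstanceNorm(), nn.ReLU(),
        nn.Conv2d(g, 2 * g, 3, stride=2, pad=1), nn.InstanceNorm(), nn.ReLU(),
        nn.Conv2d(2 * g, 4 * g, 3, stride=2, pad=1), nn.InstanceNorm(), nn.ReLU(),
        *[nn.Residual(4 * g) for _ in range(cfg.n_res_blocks)],
        nn.NearestUpsample(), nn.Conv2d(4 * g, 2 * g, 3, pad=1),
        nn.InstanceNorm(), nn.ReLU(),
        nn.NearestUpsample(), nn.Conv2d(2 * g, g, 3, pad=1),
        nn.InstanceNorm(), nn.ReLU(),
        nn.Conv2d(g, 1, 7, pad=3), nn.Tanh(),
    )


def build_discriminator(cfg: GanConfig) -> nn.Sequential:
    d = cfg.ndf
    return nn.Sequential(
        nn.Conv2d(1, d, 4, stride=2, pad=1), nn.LeakyReLU(),
        nn.Conv2d(d, 2 * d, 4, stride=2, pad=1), nn.InstanceNorm(), nn.LeakyReLU(),
        nn.Conv2d(2 * d, 4 * d, 4, stride=2, pad=1), nn.InstanceNorm(), nn.LeakyReLU(),
        nn.Conv2d(4 * d, 4 * d, 4, stride=2, pad=1), nn.InstanceNorm(), nn.LeakyReLU(),
        nn.Conv2d(4 * d, 1, 4, stride=1, pad=1),
    )


def build_networks(cfg: GanConfig) -> NetworkSet:
    gens = {name: build_generator(cfg) for name in GENERATOR_NAMES}
    discs = {name: build_discriminator(cfg) for name in DISCRIMINATOR_NAMES}
    opts = {
        name: nn.Adam(net, lr=cfg.learning_rate, beta1=cfg.ema_decay_beta1,
                      beta2=cfg.adam_beta2)
        for name, net in {**gens, **discs}.items()
    }
    nets = NetworkSet(generators=gens, discriminators=discs, optimizers=opts, cfg=cfg)
    return init_weights_glorot(nets, cfg)


def init_weights_glorot(nets: NetworkSet, cfg: GanConfig) -> NetworkSet:
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0]))
    for name in GENERATOR_NAMES + DISCRIMINATOR_NAMES:
        net = nets[name]
        if cfg.xavier_mode == "paper_global" and name in GENERATOR_NAMES:
            nn.truncated_normal_(net, rng, cfg.ni, cfg.no)
        else:
            nn.glorot_normal_(net, rng)
    return nets


# ---------------------------------------------------------------------------
# Losses


def adversarial_loss(disc_scores: np.ndarray) -> float:
    """MSE of the discriminator score grid against the real label 1."""
    s = np.asarray(disc_scores, dtype=np.float64)
    return float(np.mean((s - 1.0) ** 2))


def identity_loss(id_output: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute per-pixel error between G(b) and b."""
    a = np.asarray(id_output, dtype=np.float64)
    b = np.asarray(target, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def cycle_loss(reconstruction: np.ndarray, original: np.ndarray) -> float:
    """MAE between the round-trip reconstruction and the original."""
    return identity_loss(reconstruction, original)


def discriminator_loss(scores_fake, scores_real, convention="standard") -> float:
    f = np.asarray(scores_fake, dtype=np.float64)
    r = np.asarray(scores_real, dtype=np.float64)
    if convention == "standard":
        return float(0.5 * np.mean(f ** 2) + 0.5 * np.mean((r - 1.0) ** 2))
    if convention == "as_printed":
        return float(0.5 * np.mean((f - 1.0) ** 2) + 0.5 * np.mean(r ** 2))
    raise ValueError(f"unknown convention {convention!r}")


def coupled_multitask_loss(bundle_task1, bundle_task2, cfg: GanConfig) -> LossBundle:
    """Combine two (adv, id, cyc) trios into per-task totals and the shared max.

    total_k = adv_k + lambda_identity * id_k + lambda_cycle * cyc_k;
    shared = max(total_1, total_2). Only the arg-max task's binary-producing
    generator receives gradient from the shared loss (subgradient of max).
    """
    a1, i1, c1 = bundle_task1
    a2, i2, c2 = bundle_task2
    t1 = a1 + cfg.lambda_identity * i1 + cfg.lambda_cycle * c1
    t2 = a2 + cfg.lambda_identity * i2 + cfg.lambda_cycle * c2
    return LossBundle(adv_1=a1, id_1=i1, cyc_1=c1, adv_2=a2, id_2=i2, cyc_2=c2,
                      total_1=t1, total_2=t2, shared=max(t1, t2))


# loss gradients (w.r.t. the network output that produced them)

def _mse_grad(scores, target):
    s = scores.astype(np.float32, copy=False)
    return (2.0 / s.size) * (s - np.float32(target))


def _mae_grad(a, b):
    a32 = a.astype(np.float32, copy=False)
    return np.sign(a32 - b.astype(np.float32, copy=False)) / np.float32(a.size)


# ---------------------------------------------------------------------------
# Inference


def _to_model(img: np.ndarray) -> np.ndarray:
    """[0,1] HxW -> [-1,1] 1x1xHxW float32."""
    x = np.asarray(img, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    return x * 2.0 - 1.0


def _from_model(y: np.ndarray) -> np.ndarray:
    out = (y + 1.0) / 2.0
    return np.clip(out, 0.0, 1.0)


def infer_binary(image: np.ndarray, model: NetworkSet) -> np.ndarray:
    """Apply the raw->binary generator; returns a [0,1] membrane probability map."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a single 2D image")
    x = _to_model(img)
    y, _ = model.generators["GA2B"].forward(x)
    return _from_model(y)[0, 0]


# ---------------------------------------------------------------------------
# Training


def _batches(pool: np.ndarray, batch: int, rng: np.random.Generator):
    idx = rng.permutation(len(pool))
    for i in range(0, len(idx), batch):
        yield pool[idx[i : i + batch]]


def _sample(pool: np.ndarray, batch: int, rng: np.random.Generator):
    idx = rng.integers(0, len(pool), size=batch)
    return pool[idx]


def _task_step(g_fwd, g_rev, d_fwd, d_rev, opt_g_rev, opt_d_fwd, opt_d_rev,
               x_src, x_tgt, cfg, update_rev=True):
    """One optimisation step for a single cycle-GAN task.

    ``g_fwd`` maps source -> target(binary); its own update is deferred to the
    coupled shared loss, so this function returns the trio plus the tapes
    needed to apply that update later. ``g_rev``/discriminators update here.
    """
    conv = cfg.disc_label_convention
    # forward passes
    fake_tgt, tape_fwd = g_fwd.forward(x_src)
    id_tgt, tape_id = g_fwd.forward(x_tgt)
    fake_src, tape_rev = g_rev.forward(x_tgt)
    rec_tgt, tape_fwd_rec = g_fwd.forward(fake_src)
    id_src, tape_rev_id = g_rev.forward(x_src)
    rec_src, tape_rev_rec = g_rev.forward(fake_tgt)

    # ---- discriminators ------------------------------------------------
    for disc, opt, real, fake in ((d_fwd, opt_d_fwd, x_tgt, fake_tgt),
                                  (d_rev, opt_d_rev, x_src, fake_src)):
        s_fake, tf = disc.forward(fake)
        s_real, tr = disc.forward(real)
        disc.zero_grad()
        if conv == "standard":
            disc.backward(0.5 * _mse_grad(s_fake, 0.0), tf)
            disc.backward(0.5 * _mse_grad(s_real, 1.0), tr)
        else:  # as_printed
            disc.backward(0.5 * _mse_grad(s_fake, 1.0), tf)
            disc.backward(0.5 * _mse_grad(s_real, 0.0), tr)
        opt.step()

    # ---- forward-generator trio (update deferred to shared loss) -------
    s_fake_tgt, tape_d_fwd = d_fwd.forward(fake_tgt)
    adv = adversarial_loss(s_fake_tgt)
    idl = identity_loss(id_tgt, x_tgt)
    cyc = cycle_loss(rec_tgt, x_tgt)

    # ---- reverse generator: its own task loss ---------------------------
    if update_rev:
        s_fake_src, tape_d_rev = d_rev.forward(fake_src)
        g_rev.zero_grad()
        # adversarial: through d_rev (critic only, no disc grads)
        d_in = d_rev.backward(_mse_grad(s_fake_src, 1.0), tape_d_rev, accumulate=False)
        g_rev.backward(d_in, tape_rev)
        # identity
        g_rev.backward(cfg.lambda_identity * _mae_grad(id_src, x_src), tape_rev_id)
        # cycle: rec_src = g_rev(fake_tgt), fake_tgt treated as constant input
        g_rev.backward(cfg.lambda_cycle * _mae_grad(rec_src, x_src), tape_rev_rec)
        opt_g_rev.step()

    deferred = {
        "fake_tgt": fake_tgt, "tape_fwd": tape_fwd,
        "id_tgt": id_tgt, "tape_id": tape_id,
        "rec_tgt": rec_tgt, "tape_fwd_rec": tape_fwd_rec,
        "tape_d_fwd": tape_d_fwd, "s_fake_tgt": s_fake_tgt,
        "x_tgt": x_tgt,
    }
    return (adv, idl, cyc), deferred


def _apply_shared_update(g_fwd, opt_g_fwd, d_fwd, deferred, cfg):
    """Update the binary-producing generator of the arg-max task on its trio."""
    g_fwd.zero_grad()
    d_in = d_fwd.backward(_mse_grad(deferred["s_fake_tgt"], 1.0),
                          deferred["tape_d_fwd"], accumulate=False)
    g_fwd.backward(d_in, deferred["tape_fwd"])
    g_fwd.backward(cfg.lambda_identity * _mae_grad(deferred["id_tgt"], deferred["x_tgt"]),
                   deferred["tape_id"])
    g_fwd.backward(cfg.lambda_cycle * _mae_grad(deferred["rec_tgt"], deferred["x_tgt"]),
                   deferred["tape_fwd_rec"])
    opt_g_fwd.step()


def _as_pool(images) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=np.float32) for im in images])
    return arr[:, None] * 2.0 - 1.0  # N1HW in [-1,1]


def train(
    cfg: GanConfig,
    rcm_patches: Sequence[np.ndarray],
    gabor_patches: Sequence[np.ndarray],
    binary_samples: Sequence[np.ndarray],
    checkpoint_dir: Optional[str] = None,
    log_path: Optional[str] = None,
    nets: Optional[NetworkSet] = None,
):
    """Train the dual-task model on three unpaired image pools.

    Per step: update all four discriminators, update the reverse generators
    GB2A/GB2C on their own task losses, then update the binary-producing
    generator of the currently-worse task on the shared (max) loss.
    Checkpoints are taken every ``cfg.checkpoint_interval`` epochs and at the
    final epoch. Returns ``(checkpoints, log)`` where ``log`` is a list of
    per-epoch loss dictionaries (epoch 0 records the initial, pre-update
    losses).
    """
    for name, pool in (("rcm", rcm_patches), ("gabor", gabor_patches),
                       ("binary", binary_samples)):
        if len(pool) == 0:
            raise ValueError(f"empty {name} image pool")
    a_pool = _as_pool(rcm_patches)
    c_pool = _as_pool(gabor_patches)
    b_pool = _as_pool(binary_samples)

    if nets is None:
        nets = build_networks(cfg)
    g = nets.generators
    d = nets.discriminators
    opt = nets.optimizers
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))

    def eval_bundle(a, c, b):
        fake_b1, _ = g["GA2B"].forward(a)
        id_b1, _ = g["GA2B"].forward(b)
        fake_a, _ = g["GB2A"].forward(b)
        rec_b1, _ = g["GA2B"].forward(fake_a)
        s1, _ = d["DB1"].forward(fake_b1)
        fake_b2, _ = g["GC2B"].forward(c)
        id_b2, _ = g["GC2B"].forward(b)
        fake_c, _ = g["GB2C"].forward(b)
        rec_b2, _ = g["GC2B"].forward(fake_c)
        s2, _ = d["DB2"].forward(fake_b2)
        return coupled_multitask_loss(
            (adversarial_loss(s1), identity_loss(id_b1, b), cycle_loss(rec_b1, b)),
            (adversarial_loss(s2), identity_loss(id_b2, b), cycle_loss(rec_b2, b)),
            cfg,
        )

    log = []
    checkpoints = []

    def record(epoch, bundle):
        row = {"epoch": epoch, **{k: getattr(bundle, k) for k in
               ("adv_1", "id_1", "cyc_1", "adv_2", "id_2", "cyc_2",
                "total_1", "total_2", "shared")}}
        log.append(row)

    def take_checkpoint(epoch):
        ck = Checkpoint(epoch=epoch, state=nets.state_dict(), cfg=cfg)
        checkpoints.append(ck)
        if checkpoint_dir is not None:
            Path(checkpoint_dir).mkdir(parents=True, exist_ok=True)
            ck.save(Path(checkpoint_dir) / f"ckpt_epoch{epoch:05d}.npz")

    # epoch-0 losses on a deterministic probe batch
    probe = (a_pool[: cfg.batch_size], c_pool[: cfg.batch_size], b_pool[: cfg.batch_size])
    record(0, eval_bundle(*probe))

    steps_per_epoch = max(1, math.ceil(len(b_pool) / cfg.batch_size))
    aborted = False
    for epoch in range(1, cfg.epochs + 1):
        epoch_bundle = None
        for b in _batches(b_pool, cfg.batch_size, rng):
            a = _sample(a_pool, len(b), rng)
            c = _sample(c_pool, len(b), rng)
            trio1, def1 = _task_step(
                g["GA2B"], g["GB2A"], d["DB1"], d["DA"],
                opt["GB2A"], opt["DB1"], opt["DA"], a, b, cfg)
            trio2, def2 = _task_step(
                g["GC2B"], g["GB2C"], d["DB2"], d["DC"],
                opt["GB2C"], opt["DB2"], opt["DC"], c, b, cfg)
            bundle = coupled_multitask_loss(trio1, trio2, cfg)
            if not np.isfinite(bundle.shared):
                aborted = True
                break
            if bundle.argmax_task == 1:
                _apply_shared_update(g["GA2B"], opt["GA2B"], d["DB1"], def1, cfg)
            else:
                _apply_shared_update(g["GC2B"], opt["GC2B"], d["DB2"], def2, cfg)
            epoch_bundle = bundle
        if aborted:
            break
        record(epoch, epoch_bundle)
        if epoch % cfg.checkpoint_interval == 0:
            take_checkpoint(epoch)

    if not checkpoints or checkpoints[-1].epoch != (log[-1]["epoch"] if log else 0):
        take_checkpoint(log[-1]["epoch"] if log else 0)

    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
            writer.writeheader()
            writer.writerows(log)
    return checkpoints, log


def restore_networks(checkpoint: Checkpoint) -> NetworkSet:
    nets = build_networks(checkpoint.cfg)
    nets.load_state_dict(checkpoint.state)
    return nets


def select_checkpoint(checkpoints, val_images, val_centers, metric_cfg=None,
                      postprocess_fn=None):
    """Pick the checkpoint with the best median F1 on the validation set.

    Runs inference plus the post-processing chain for every checkpoint and
    scores predicted centers against ground truth with d-accuracy. Ties are
    broken in favour of the later epoch.
    """
    from . import evalmetrics
    from .pipeline import infer_and_extract_centers

    if len(checkpoints) == 0:
        raise ValueError("no checkpoints")
    metric_cfg = metric_cfg or {}
    d = metric_cfg.get("d", 10.0)
    layer = metric_cfg.get("layer", "SS")

    best = None
    for ck in checkpoints:
        nets = restore_networks(ck)
        results = []
        for img, gt in zip(val_images, val_centers):
            if postprocess_fn is not None:
                pred = postprocess_fn(infer_binary(img, nets))
            else:
                pred = infer_and_extract_centers(img, nets, layer=layer)
            results.append(evalmetrics.match_detections(pred, gt, d=d))
        med = evalmetrics.summarize_images(results)["median_f1"]
        if best is None or med > best[0] or (med == best[0] and ck.epoch >= best[1].epoch):
            best = (med, ck)
    return best[1]
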