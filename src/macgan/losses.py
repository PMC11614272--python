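"""Tversky loss and the conditional adversarial objectives.

The Tversky index generalizes Dice with asymmetric false-positive /
false-negative weights,

    T(y, g) = ΣTP / (ΣTP + α·ΣFP + β·ΣFN),
    TPᵢ = yᵢgᵢ,  FPᵢ = (1−yᵢ)gᵢ,  FNᵢ = yᵢ(1−gᵢ),

with α = 0.7, β = 0.3 by default (penalizing false positives harder while
keeping recall on the small tumor class); α = β = 0.5 recovers soft Dice.
The training loss is 1 − T.

Two adversarial modes are provided.  ``nolog`` drops the log from the GAN
objective (the Wasserstein-distance rationale: stabler gradients with a
bounded critic), so the discriminator minimizes −E[D(real)] + E[D(fake)]
and the generator minimizes −E[D(fake)] + λ·(1 − T).  ``bce`` is the
classical ones/zeros cross-entropy reading.  No gradient penalty or weight
clipping is applied in either mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn.tensor import Tensor, as_tensor, log, tmean, tsum

__all__ = ["TverskyParams", "tversky_index", "tversky_loss",
           "discriminator_loss", "generator_loss"]

_ADV_MODES = ("nolog", "bce")
_EPS = 1e-7  # guards log() in bce mode


@dataclass
class TverskyParams:
    alpha: float = 0.7   # false-positive weight
    beta: float = 0.3    # false-negative weight
    smooth: float = 1e-6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.smooth <= 0:
            raise ValueError(f"invalid Tversky parameters {self}")


def _pair(y, g):
    y, g = as_tensor(y), as_tensor(g)
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch {y.shape} vs {g.shape}")
    return y, g


def tversky_index(y, g, params: TverskyParams = TverskyParams()) -> Tensor:
    """Tversky similarity in [0, 1]; 1 iff the prediction is perfect.

    ``y`` is the binary reference, ``g`` the predicted probabilities; inputs
    may be numpy arrays or tensors (gradients flow through ``g``).
    """
    y, g = _pair(y, g)
    tp = tsum(y * g)
    fp = tsum((1.0 - y) * g)
    fn = tsum(y * (1.0 - g))
    s = params.smooth
    return (tp + s) / (tp + params.alpha * fp + params.beta * fn + s)


def tversky_loss(y, g, params: TverskyParams = TverskyParams()) -> Tensor:
    """1 − Tversky index; 0 iff perfect, decreases as overlap improves."""
    return 1.0 - tversky_index(y, g, params)


def _check_mode(mode):
    if mode not in _ADV_MODES:
        raise ValueError(f"mode must be one of {_ADV_MODES}, got {mode!r}")


def _bce(p, target_ones: bool) -> Tensor:
    # probabilities from a sigmoid are in (0, 1); _EPS guards the endpoints
    p = as_tensor(p)
    if target_ones:
        return -tmean(log(p + _EPS))
    return -tmean(log(1.0 - p + _EPS))


def discriminator_loss(d_real, d_fake, mode: str = "nolog") -> Tensor:
    """Critic objective (to minimize).

    ``nolog``: −mean(D(real)) + mean(D(fake)).  ``bce``: cross-entropy of
    D(real) against ones plus D(fake) against zeros.
    """
    _check_mode(mode)
    d_real, d_fake = as_tensor(d_real), as_tensor(d_fake)
    if d_real.data.size == 0 or d_fake.data.size == 0:
        raise ValueError("empty discriminator batch")
    if mode == "nolog":
        return -tmean(d_real) + tmean(d_fake)
    return _bce(d_real, True) + _bce(d_fake, False)


def generator_loss(d_fake, y, g, params: TverskyParams = TverskyParams(),
                   mode: str = "nolog", lam: float = 1.0) -> Tensor:
    """Generator objective: adversarial term + λ·(1 − Tversky index)."""
    _check_mode(mode)
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    d_fake = as_tensor(d_fake)
    if d_fake.data.size == 0:
        raise ValueError("empty discriminator batch")
    adv = -tmean(d_fake) if mode == "nolog" else _bce(d_fake, True)
    return adv + lam * tversky_loss(y, g, params)
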