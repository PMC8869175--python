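"""WGAN-GP loss terms with the auxiliary-classifier extension.

The critic minimizes  E[D(fake)] - E[D(real)] + GP + lambda_cls * CE
where GP is the gradient penalty  sigma * E[(||grad_xhat D(xhat)||_2 - 1)^2]
evaluated on random interpolates between real and fake batches, and CE is
the class cross-entropy of the auxiliary head on real and on fake samples
(fake samples keep the label the generator was conditioned on).

The generator minimizes  -E[D(fake)] + lambda_cls * CE(fake).

The adversarial "source" term is the Wasserstein objective itself; a
probabilistic source log-likelihood is additionally reported for
monitoring only, obtained by mapping the unbounded critic scores through
a logistic function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import tensor as T
from .engine.tensor import Tensor


@dataclass
class LossTerms:
    """Scalar loss components recorded once per training iteration."""

    critic_wasserstein: float
    gradient_penalty: float
    class_loss_real: float
    class_loss_fake: float
    generator_adversarial: float
    generator_class: float
    source_loglik: float = 0.0  # monitoring only

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)

    def finite(self) -> bool:
        return all(np.isfinite(v) for v in self.__dict__.values())


def critic_wasserstein_loss(real_scores, fake_scores) -> Tensor:
    """mean(fake) - mean(real); minimized by the critic."""
    real_scores = T.as_tensor(real_scores)
    fake_scores = T.as_tensor(fake_scores)
    if real_scores.size == 0 or fake_scores.size == 0:
        raise ValueError("score vectors must be non-empty")
    return T.mean_(fake_scores) - T.mean_(real_scores)


def interpolate(real, fake, eps) -> Tensor:
    """Per-sample convex combination eps*real + (1-eps)*fake."""
    real_t = T.as_tensor(real)
    fake_t = T.as_tensor(fake)
    if real_t.shape != fake_t.shape:
        raise ValueError("real and fake batches must have equal shapes")
    eps = np.asarray(eps, dtype=real_t.dtype).reshape(
        (-1,) + (1,) * (real_t.ndim - 1))
    if np.any(eps < 0) or np.any(eps > 1):
        raise ValueError("eps must lie in [0, 1]")
    e = Tensor(np.broadcast_to(eps, real_t.shape).copy())
    return real_t * e + fake_t * (1.0 - e)


def gradient_penalty(critic_fn, x_hat, sigma: float = 10.0) -> Tensor:
    """sigma * E[(||grad_x D(x)||_2 - 1)^2] at x = x_hat.

    critic_fn maps an image tensor to the source-score head (a callable
    returning either a score Tensor or an object with ``source_score``).
    The result is differentiable with respect to the critic weights.
    """
    x = x_hat if isinstance(x_hat, Tensor) else Tensor(x_hat)
    if not x.requires_grad:
        x = Tensor(x.data, requires_grad=True)
    out = critic_fn(x)
    score = getattr(out, "source_score", out)
    if not score.requires_grad:  # critic constant in its input
        return Tensor(np.asarray(float(sigma)))
    (gx,) = T.grad(T.sum_(score), [x], create_graph=True)
    if gx is None:
        return Tensor(np.asarray(float(sigma)))
    if not np.all(np.isfinite(gx.data)):
        raise FloatingPointError("non-finite critic input gradient")
    sq = T.sum_(gx * gx, axis=tuple(range(1, x.ndim)))
    norms = T.power(sq, 0.5)
    dev = norms - 1.0
    return T.mean_(dev * dev) * float(sigma)


def class_log_likelihood(class_logits, labels) -> Tensor:
    """Mean log-probability of the true class (non-positive)."""
    logits = T.as_tensor(class_logits)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise ValueError("label out of range")
    logp = T.log_softmax(logits, axis=1)
    rows = T.take_rows(T.reshape(logp, (-1,)),
                       np.arange(len(labels)) * logits.shape[1] + labels)
    return T.mean_(rows)


def source_class_loglik(critic_out_real, critic_out_fake,
                        labels_real, labels_fake) -> tuple[float, float]:
    """(S_L surrogate, C_L) as floats for monitoring.

    C_L is the class log-likelihood summed over the real and fake terms;
    a fake sample's "true" class is the label the generator was
    conditioned on.  S_L maps the Wasserstein scores through a logistic
    function, because an unbounded critic has no native source
    probability; it is reported, never optimized.
    """
    with T.no_grad():
        cl = (class_log_likelihood(critic_out_real.class_logits, labels_real)
              + class_log_likelihood(critic_out_fake.class_logits,
                                     labels_fake))
        # log sigma(s_real) + log(1 - sigma(s_fake)), stably
        sl = (-T.mean_(T.softplus(-critic_out_real.source_score))
              - T.mean_(T.softplus(critic_out_fake.source_score)))
    return float(sl.data), float(cl.data)


def critic_loss(critic, real_images, real_labels, fake_images, fake_labels,
                sigma: float, lambda_cls: float,
                eps) -> tuple[Tensor, dict[str, float]]:
    """Total critic objective and its scalar components."""
    out_real = critic(real_images)
    out_fake = critic(fake_images)
    w = critic_wasserstein_loss(out_real.source_score, out_fake.source_score)
    if sigma > 0:
        x_hat = interpolate(real_images, fake_images, eps)
        gp = gradient_penalty(critic, Tensor(x_hat.data, requires_grad=True),
                              sigma)
    else:
        gp = Tensor(0.0)
    ce_real = -class_log_likelihood(out_real.class_logits, real_labels)
    ce_fake = -class_log_likelihood(out_fake.class_logits, fake_labels)
    total = w + gp + (ce_real + ce_fake) * lambda_cls
    sl, _ = source_class_loglik(out_real, out_fake, real_labels, fake_labels)
    terms = {
        "critic_wasserstein": float(w.data),
        "gradient_penalty": float(gp.data),
        "class_loss_real": float(ce_real.data),
        "class_loss_fake": float(ce_fake.data),
        "source_loglik": sl,
        "aux_accuracy_real": float(np.mean(
            np.argmax(out_real.class_logits.data, axis=1) == real_labels)),
    }
    return total, terms


def generator_loss(critic, fake_images, fake_labels,
                   lambda_cls: float) -> tuple[Tensor, dict[str, float]]:
    """-E[D(fake)] + lambda_cls * CE(fake); graph reaches the generator."""
    out_fake = critic(fake_images)
    adv = -T.mean_(out_fake.source_score)
    ce = -class_log_likelihood(out_fake.class_logits, fake_labels)
    total = adv + ce * lambda_cls
    return total, {
        "generator_adversarial": float(adv.data),
        "generator_class": float(ce.data),
    }


def total_losses(real_batch, fake_batch, critic, sigma: float = 10.0,
                 lambda_cls: float = 1.0, seed: int = 0) -> LossTerms:
    """Evaluate every loss component on one pair of batches (no update)."""
    rng = np.random.default_rng(seed)
    real = T.as_tensor(real_batch.images)
    fake = T.as_tensor(fake_batch.images)
    eps = rng.uniform(size=len(real_batch))
    _, c_terms = critic_loss(critic, real, real_batch.labels, fake,
                             fake_batch.labels, sigma, lambda_cls, eps)
    _, g_terms = generator_loss(critic, fake, fake_batch.labels, lambda_cls)
    return LossTerms(
        critic_wasserstein=c_terms["critic_wasserstein"],
        gradient_penalty=c_terms["gradient_penalty"],
        class_loss_real=c_terms["class_loss_real"],
        class_loss_fake=c_terms["class_loss_fake"],
        generator_adversarial=g_terms["generator_adversarial"],
        generator_class=g_terms["generator_class"],
        source_loglik=c_terms["source_loglik"],
    )
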