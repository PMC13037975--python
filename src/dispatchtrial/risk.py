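"""Composite risk scoring and synthetic model predictions.

The deployed decision-support tool predicted four proxy outcomes per
patient (abnormal primary assessment, lights-and-sirens transport,
prehospital intervention, 72 h admission or 30 d mortality) and combined
them into a composite score with weights 4:2:1:1.  The trained text/
gradient-boosting model itself is out of scope here; in its place
:func:`synthetic_predictions` emits probabilities driven by each patient's
latent acuity plus independent noise, with the noise SD controlling how
often the composite ranks the truly sickest patient first (default
calibration: ~70 % of pairwise comparisons name the highest-NEWS patient,
matching the operating point assumed in the trial's sample-size work).

Only ranks matter downstream, so the combination rule is implemented as a
weighted mean of the four probabilities (weights normalized to sum 1); any
strictly monotone variant would yield the identical trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import PROXY_OUTCOMES, _PROXY_BASE_LOGIT
from .config import ConfigError, GeneratorConfig

DEFAULT_WEIGHTS = (4.0, 2.0, 1.0, 1.0)


@dataclass(frozen=True)
class OutcomePredictions:
    """Predicted probabilities for the four proxy outcomes."""

    p_abnormal_assessment: float
    p_lights_sirens: float
    p_intervention: float
    p_admission_mortality: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.p_abnormal_assessment,
                self.p_lights_sirens,
                self.p_intervention,
                self.p_admission_mortality,
            ]
        )


def composite_score(preds, weights=DEFAULT_WEIGHTS):
    """Weighted mean of the four outcome probabilities.

    ``preds`` may be an :class:`OutcomePredictions`, a length-4 sequence, or
    an (n, 4) array.  Weights must be positive; they are normalized to sum
    to 1, so the score is invariant in rank under positive rescaling.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ConfigError("weights must be a 4-vector")
    if (w <= 0).any():
        raise ConfigError("weights must be positive")
    w = w / w.sum()
    if isinstance(preds, OutcomePredictions):
        p = preds.as_array()
    else:
        p = np.asarray(preds, dtype=float)
    if p.ndim == 1:
        return float(p @ w)
    return p @ w


def calibrate_confidence_cutoff(gaps) -> float:
    """Median top-two score gap: the high/low confidence cutoff.

    Gaps at or above the cutoff are high-confidence.  By the property of
    the empirical median this splits the calibration set 50/50 to within
    one element.
    """
    gaps = np.asarray(list(gaps), dtype=float)
    if gaps.size < 2:
        raise ConfigError("need at least 2 calibration gaps")
    return float(np.median(gaps))


def classify_confidence(gaps, cutoff: float) -> np.ndarray:
    gaps = np.asarray(gaps, dtype=float)
    return np.where(gaps >= cutoff, "high", "low")


def synthetic_predictions(
    patients: pd.DataFrame, config: GeneratorConfig, weights=DEFAULT_WEIGHTS
) -> pd.DataFrame:
    """Per-patient predicted outcome probabilities and composite score.

    Each probability is a logistic transform of latent acuity plus
    independent N(0, model_noise_sd) noise on the logit scale, using the
    same baseline prevalences that generate the realized proxy outcomes.
    """
    rng = config.rng("predictions")
    a = patients["latent_acuity"].to_numpy()
    probs = np.empty((len(a), 4))
    for k, name in enumerate(PROXY_OUTCOMES):
        noise = rng.normal(0.0, config.model_noise_sd, size=len(a))
        probs[:, k] = expit(_PROXY_BASE_LOGIT[name] + a + noise)
    out = pd.DataFrame({"patient_id": patients["patient_id"].to_numpy()})
    for k, name in enumerate(PROXY_OUTCOMES):
        out[f"p_{name}"] = probs[:, k]
    out["composite_score"] = composite_score(probs, weights)
    return out


def observed_composite_outcome(patients: pd.DataFrame, weights=DEFAULT_WEIGHTS) -> np.ndarray:
    """Composite outcome *score* from the realized binary proxy outcomes.

    Used by the secondary hypothesis: the same 4:2:1:1 weighting applied to
    what actually happened to the patient rather than to predictions.
    """
    y = patients[list(PROXY_OUTCOMES)].to_numpy(dtype=float)
    return composite_score(y, weights)


def calibrate_compliance(target_agreement: float, chance_agreement: float) -> float:
    """Deferral probability reproducing a target observed model agreement.

    In the intervention arm dispatchers defer to the model with probability
    ``c`` and otherwise follow the nurses' own choice, which coincides with
    the model's pick at the chance rate ``q`` (the control-arm agreement).
    Observed agreement is then ``c + (1 - c) q``; solving for ``c`` keeps
    the behavioral parameter distinct from the observed rate.
    """
    if not (0.0 <= chance_agreement < 1.0):
        raise ConfigError("chance_agreement must lie in [0, 1)")
    if not (chance_agreement <= target_agreement <= 1.0):
        raise ConfigError("target agreement must lie between chance agreement and 1")
    return (target_agreement - chance_agreement) / (1.0 - chance_agreement)
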