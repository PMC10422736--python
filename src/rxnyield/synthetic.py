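"""Synthetic C-N coupling datasets with known ground truth.

Emulates the structure of a plate-based amination screen: substrates are
substituted benzenoid (Ph) or pyridyl (Py) amines and aryl bromides, the
product is the diarylamine formed by joining the two templates, and the
outcome is a UV-ratio-like value in [0, 1]. The latent outcome is a smooth
deterministic function of per-substrate effects,

    y0 = sigmoid(base + e_amine + e_bromide + w_int * e_amine * e_bromide) ** skew

to which truncated Gaussian noise is added before clipping to [0, 1].
Raising the logistic to the ``skew`` power pushes mass toward low values,
reproducing the heavily left-skewed outcome distributions typical of
real screens (roughly half of all reactions below 0.2 at the defaults).

Substrate effects are drawn once from the seeded generator and persisted in
the ground-truth table, so recovery of the latent structure is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Template vocabularies: amines start with "N", bromides with "Br", so the
# product SMILES is a pure string join (amine N substituted by the bromide's
# aryl part). Half of each list is benzenoid, half pyridyl; substituents
# span electron-donating and electron-withdrawing groups at o/m/p positions.
DEFAULT_AMINES: dict[str, str] = {
    "Nc1ccccc1": "Ph",
    "Nc1ccc(C)cc1": "Ph",
    "Nc1ccc(OC)cc1": "Ph",
    "Nc1cccc(F)c1": "Ph",
    "Nc1ccc(C(F)(F)F)cc1": "Ph",
    "Nc1ccc(C#N)cc1": "Ph",
    "Nc1ccccn1": "Py",
    "Nc1cccnc1": "Py",
    "Nc1ccncc1": "Py",
    "Nc1ccc(C)cn1": "Py",
    "Nc1ccc(F)cn1": "Py",
    "Nc1ccc(OC)nc1": "Py",
}
DEFAULT_BROMIDES: dict[str, str] = {
    "Brc1ccccc1": "Ph",
    "Brc1ccc(C)cc1": "Ph",
    "Brc1ccc(OC)cc1": "Ph",
    "Brc1cccc(F)c1": "Ph",
    "Brc1ccc(C(F)(F)F)cc1": "Ph",
    "Brc1ccc(C#N)cc1": "Ph",
    "Brc1ccccn1": "Py",
    "Brc1cccnc1": "Py",
    "Brc1ccncc1": "Py",
    "Brc1ccc(C)cn1": "Py",
    "Brc1ccc(F)nc1": "Py",
    "Brc1ccc(OC)cn1": "Py",
}

_GROUP_BY_CLASS = {
    ("Ph", "Ph"): "G1",
    ("Ph", "Py"): "G2",
    ("Py", "Ph"): "G3",
    ("Py", "Py"): "G4",
}


@dataclass
class GeneratorConfig:
    """Settings of the synthetic screen.

    noise_sd is the standard deviation of the (2-sigma-truncated) Gaussian
    measurement noise on the unit-range outcome; skew >= 1 raises the
    logistic latent to that power, increasing left-skew; effect_sd scales
    the spread of per-substrate latent effects.
    """

    n: int = 500
    seed: int = 0
    noise_sd: float = 0.05
    skew: float = 3.0
    base: float = 0.0
    effect_sd: float = 1.0
    interaction: float = 0.5
    amine_vocab: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_AMINES))
    bromide_vocab: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BROMIDES)
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.skew <= 0:
            raise ValueError("skew must be > 0")
        if not self.amine_vocab or not self.bromide_vocab:
            raise ValueError("substrate vocabularies must be non-empty")
        for s in self.amine_vocab:
            if not s.startswith("N"):
                raise ValueError(f"amine template must start with 'N': {s!r}")
        for s in self.bromide_vocab:
            if not s.startswith("Br"):
                raise ValueError(f"bromide template must start with 'Br': {s!r}")


def join_product(amine_smiles: str, bromide_smiles: str) -> str:
    """Diarylamine product SMILES from the two substrate templates."""
    aryl = bromide_smiles[2:]
    return amine_smiles.replace("N", f"N({aryl})", 1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a synthetic reaction table and its ground-truth effect table.

    Returns ``(data, truth)``. ``data`` has one row per reaction with
    columns amine_smiles, bromide_smiles, product_smiles, ratio_uv (noisy,
    in [0,1]), ground_truth (noiseless) and group (G1-G4). ``truth`` lists
    the latent effect of every substrate.
    """
    rng = np.random.default_rng(config.seed)
    amines = list(config.amine_vocab)
    bromides = list(config.bromide_vocab)
    amine_eff = rng.normal(0.0, config.effect_sd, size=len(amines))
    bromide_eff = rng.normal(0.0, config.effect_sd, size=len(bromides))

    ai = rng.integers(0, len(amines), size=config.n)
    bi = rng.integers(0, len(bromides), size=config.n)
    latent = (
        config.base
        + amine_eff[ai]
        + bromide_eff[bi]
        + config.interaction * amine_eff[ai] * bromide_eff[bi]
    )
    y0 = _sigmoid(latent) ** config.skew
    noise = np.clip(
        rng.normal(0.0, config.noise_sd or 1.0, size=config.n),
        -2 * config.noise_sd,
        2 * config.noise_sd,
    )
    if config.noise_sd == 0:
        noise = np.zeros(config.n)
    y = np.clip(y0 + noise, 0.0, 1.0)

    rows = []
    for k in range(config.n):
        a, b = amines[ai[k]], bromides[bi[k]]
        rows.append(
            {
                "amine_smiles": a,
                "bromide_smiles": b,
                "product_smiles": join_product(a, b),
                "ratio_uv": y[k],
                "ground_truth": y0[k],
                "group": _GROUP_BY_CLASS[
                    (config.amine_vocab[a], config.bromide_vocab[b])
                ],
            }
        )
    data = pd.DataFrame(rows)

    truth = pd.DataFrame(
        [
            {"role": "amine", "smiles": s, "aromatic_class": c, "effect": e}
            for (s, c), e in zip(config.amine_vocab.items(), amine_eff)
        ]
        + [
            {"role": "bromide", "smiles": s, "aromatic_class": c, "effect": e}
            for (s, c), e in zip(config.bromide_vocab.items(), bromide_eff)
        ]
    )
    return data, truth
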