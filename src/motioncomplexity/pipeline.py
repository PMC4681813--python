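"""End-to-end computation of the five complexity measures per pattern.

For each motion pattern this produces one record with

* ``gp``:  entropic complexity of the Gaussian-process fit (nats),
* ``pmp``: entropy of the PMP predictive trajectory distribution (nats),
* ``lzc``: normalised LZ-76 complexity of a sampled symbol corpus,
* ``emc``: effective measure complexity of the same corpus (bits),
* ``var``: across-repetition trajectory variance (cm^2),

the container consumed by the correlation stage.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .gp_complexity import fit_gp_pattern
from .info_measures import emc, lz76_normalized
from .pmp_model import BasisConfig, fit_pmp_patterns, pmp_complexity
from .symbolic_dynamics import build_corpus
from .trajectory_core import MotionPattern, pattern_variance

__all__ = ["compute_complexity_records"]


def compute_complexity_records(
    patterns: Sequence[MotionPattern],
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compute all five complexity measures for a pattern collection.

    The PMP prior is pooled over the whole collection (empirical Bayes);
    symbol corpora are sampled from each pattern's fitted PMP model until
    ``config.min_transitions`` transitions are reached.  ``seed`` controls
    corpus sampling and defaults to ``config.seed``.
    """
    cfg = config or AnalysisConfig()
    if seed is None:
        seed = cfg.seed
    resampled = [p.resampled(cfg.T) for p in patterns]
    basis = BasisConfig(n=cfg.pmp_n_basis, h=cfg.pmp_h)
    models = fit_pmp_patterns(
        resampled, basis=basis, kappa0=cfg.kappa0, nu0=cfg.nu0, sigma_tau=cfg.sigma_tau
    )
    seeds = np.random.SeedSequence(seed).spawn(len(resampled))
    rows = []
    for pattern, model, ss in zip(resampled, models, seeds):
        gp = fit_gp_pattern(pattern, concat=cfg.gp_concat)
        corpus = build_corpus(
            model,
            cfg.workspace,
            min_transitions=cfg.min_transitions,
            seed=int(ss.generate_state(1)[0] % (2**31)),
            T=cfg.T,
        )
        emc_value, _ = emc(corpus, l_max=cfg.l_max)
        rows.append(
            {
                "subject": pattern.subject_id,
                "trial": pattern.trial_id,
                "gp": gp.complexity,
                "pmp": pmp_complexity(model, cfg.T),
                "lzc": lz76_normalized(corpus, alphabet_size=4),
                "emc": emc_value,
                "var": pattern_variance(pattern),
            }
        )
    return pd.DataFrame(rows)
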