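"""Independent brute-force oracles used to cross-check the implementation.

Everything here applies the defining rules literally, one patient or
one candidate at a time, without reusing any vectorized code from the
package under test.
"""

import numpy as np
import pandas as pd


def brute_force_gene_scores(disc: pd.DataFrame, died: pd.Series) -> pd.DataFrame:
    """Rule-by-rule concordance scores, one (gene, patient) pair at a time."""
    records = {}
    for gene in disc.index:
        poor = 0
        good = 0
        for patient in died.index:
            level = int(disc.at[gene, patient])
            outcome = bool(died.loc[patient])
            # poor-prognosis rules
            if level == 1 and outcome:
                poor += 1
            elif level == -1 and not outcome:
                poor += 1
            elif level == -1 and outcome:
                poor -= 1
            elif level == 1 and not outcome:
                poor -= 1
            # good-prognosis rules, stated independently (not as -poor)
            if level == 1 and not outcome:
                good += 1
            elif level == -1 and outcome:
                good += 1
            elif level == -1 and not outcome:
                good -= 1
            elif level == 1 and outcome:
                good -= 1
        records[gene] = (poor, good)
    return pd.DataFrame.from_dict(records, orient="index", columns=["poor", "good"])


def brute_force_best_cutoff(scores: np.ndarray, died: np.ndarray):
    """Exhaustive scan over every candidate cutoff; returns (cutoff, sens, spec)."""
    uniq = np.unique(scores)
    candidates = [-np.inf] + [(a + b) / 2 for a, b in zip(uniq[:-1], uniq[1:])] + [np.inf]
    best = None
    for c in candidates:
        sens = sum(1 for s, d in zip(scores, died) if d and s > c) / max(died.sum(), 1)
        spec = sum(1 for s, d in zip(scores, died) if not d and s <= c) / max((~died).sum(), 1)
        if best is None or sens + spec > best[3] + 1e-15:
            best = (c, sens, spec, sens + spec)
    return best


def hand_logrank(times_a, events_a, times_b, events_b) -> float:
    """Two-group log-rank chi-square from the observed-minus-expected tables."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b]).astype(bool)
    group_a = np.concatenate([np.ones(len(times_a), bool), np.zeros(len(times_b), bool)])
    observed_minus_expected = 0.0
    variance = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & group_a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & group_a).sum()
        observed_minus_expected += d_a - d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return observed_minus_expected**2 / variance
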