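"""Desk-scale benchmark runs on synthetic corpora.

These drive the repository's verification story: a strong-signal corpus
must train to high AUC, a label-shuffled control must stay near chance,
and recursive feature elimination must recover a planted informative
subset.  Network widths and epoch counts use the compact configuration
(see :meth:`thermoseq.model.ModelConfig.compact`).
"""

from __future__ import annotations

import numpy as np

from .descriptors import ProteinFeaturizer
from .metrics import auc_rank
from .model import ModelConfig, ThermoNetClassifier
from .selection import rfecv
from .synthetic_data import GeneratorSpec, generate_corpus, generate_feature_table


def synthetic_end_to_end(seed: int = 7, n_per_class: int = 400,
                         epochs: int = 10, test_fraction: float = 0.2) -> dict:
    """Featurize, train and evaluate on a strong-signal corpus plus a
    label-shuffled control.

    One corpus is generated and featurized once; two classifiers are then
    trained — one on the true labels, one on a seeded permutation — and
    scored on a held-out stratified split.  Returns ``auc_signal``,
    ``auc_shuffled`` and the split sizes.
    """
    records = generate_corpus(GeneratorSpec(n_pos=n_per_class,
                                            n_neg=n_per_class, seed=seed))
    y = np.array([1 if r.label == "thermophilic" else 0 for r in records])
    seqs = [r.sequence for r in records]
    bio = ProteinFeaturizer().fit(seqs).transform(seqs)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    n_test = int(round(test_fraction * len(records)))
    test_idx, train_idx = idx[:n_test], idx[n_test:]

    out = {"n_train": len(train_idx), "n_test": len(test_idx)}
    for arm, labels in (("signal", y), ("shuffled", rng.permutation(y))):
        cfg = ModelConfig.compact(seed=seed, epochs=epochs)
        clf = ThermoNetClassifier.from_config(cfg)
        clf.fit([seqs[i] for i in train_idx], labels[train_idx],
                biofeatures=bio[train_idx])
        scores = clf.predict_proba([seqs[i] for i in test_idx],
                                   biofeatures=bio[test_idx])[:, 1]
        out[f"auc_{arm}"] = auc_rank(scores, labels[test_idx])
    return out


def selection_recovery(seed: int = 3, n: int = 400, p: int = 100,
                       n_informative: int = 10) -> dict:
    """RFECV on a feature table with a planted informative subset.

    Returns the number of informative features recovered, the selected
    subset size, and the mean-CV-AUC gap between the selected subset and
    the full panel.
    """
    X, y, names, informative = generate_feature_table(n, p, n_informative, seed)
    result = rfecv(X, y, names, n_folds=10, step=8, seed=seed)
    recovered = set(result.selected_names) & set(informative)
    full_score = result.cv_curve[max(result.cv_curve)]
    return {
        "n_informative": n_informative,
        "n_recovered": len(recovered),
        "n_selected": result.n_selected,
        "selected_cv_auc": result.best_score(),
        "full_panel_cv_auc": full_score,
        "cv_gap": result.best_score() - full_score,
    }
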