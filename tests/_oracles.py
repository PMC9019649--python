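"""Independent test oracles, kept deliberately naive and separate from the
package implementations they check."""

from collections import Counter

import numpy as np


def brute_force_f_near(sentences, node_words, span, skip_stopwords=False):
    """Quadratic-time window oracle: for every (node, token) pair in a
    sentence, decide membership by literally counting position-consuming
    tokens along the path from the node to the candidate (inclusive)."""
    near = Counter()
    for sent in sentences:
        toks = sent.tokens
        node_positions = [i for i, t in enumerate(toks) if t.surface in node_words]
        for j, tok in enumerate(toks):
            if tok.is_article or (skip_stopwords and tok.is_stopword):
                continue  # never emitted, never a window terminus
            if tok.is_stopword or tok.surface in node_words:
                continue  # consumes a position but is not emitted
            in_any_window = False
            for i in node_positions:
                if i == j:
                    continue
                step = 1 if j > i else -1
                consumed = 0
                for k in range(i + step, j + step, step):
                    u = toks[k]
                    if not (u.is_article or (skip_stopwords and u.is_stopword)):
                        consumed += 1
                if consumed <= span:
                    in_any_window = True
                    break
            if in_any_window:
                near[(sent.year, tok.surface)] += 1
    return near


def brute_force_mi(f_near, n_tokens, f_node, f_colloc, span):
    """MI as a probability ratio: observed co-occurrence probability per
    window slot over the collocate's marginal probability."""
    p_near = f_near / (f_node * 2 * span)
    p_marginal = f_colloc / n_tokens
    return float(np.log2(p_near / p_marginal))


def normal_equations_ols(design, response):
    """Explicit (X'X)^-1 X'y solve with textbook classical SEs."""
    X = np.asarray(design, float)
    y = np.asarray(response, float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    n, p = X.shape
    sigma2 = float(resid @ resid) / (n - p)
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


def variance_oracle_alpha(matrix):
    """Spreadsheet-style Cronbach's alpha: column variances and the variance
    of row totals, each via the explicit sum-of-squares formula."""
    rows = [list(map(float, r)) for r in matrix]
    n = len(rows)
    k = len(rows[0])

    def var(values):
        m = sum(values) / len(values)
        return sum((v - m) ** 2 for v in values) / (len(values) - 1)

    col_vars = sum(var([r[j] for r in rows]) for j in range(k))
    total_var = var([sum(r) for r in rows])
    return (k / (k - 1)) * (1 - col_vars / total_var)


# >= 20 handcrafted sentences exercising article exclusion, span truncation,
# and the sentence-boundary rule (node word: "elderly").
HANDCRAFTED_TEXTS = [
    "The elderly suffer dementia.",
    "He left. Elderly thrive.",
    "Elderly people enjoy quiet mornings.",
    "Many nurses help the elderly daily.",
    "An elderly man crossed the wide bridge slowly yesterday evening alone.",
    "Volunteers visited elderly residents.",
    "The frail elderly widow smiled.",
    "Doctors say the elderly need exercise. Gyms opened downtown.",
    "Storms came. The elderly stayed indoors. Streets flooded badly.",
    "One two three four five six seven elderly eight nine ten eleven twelve thirteen fourteen.",
    "The a an elderly the an a survived.",
    "Elderly elderly met elderly.",
    "Paint dried slowly on the old fence near the elderly gardener.",
    "She gave the elderly neighbour a warm blanket and some soup.",
    "Elderly!",
    "Is the elderly couple happy?",
    "Before dawn the elderly fisherman mended torn nets beside calm water.",
    "Children ran past. An elderly woman waved. Dogs barked loudly.",
    "Some elderly drivers renewed licences after short vision tests downtown.",
    "The committee discussed housing. Elderly tenants requested repairs. Funding arrived late.",
    "Very elderly patients with chronic rheumatism received careful bedside attention.",
    "Up the long winding hill walked an elderly postman whistling cheerfully.",
]
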