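"""Model-free exploration: trace-space MDS and imaging-field structure.

Embeds the full drift-corrected traces with classical MDS on the
rank-correlation distance d_ij = (1 - rho_ij)/2, ranks embedding dimensions
by how strongly they separate the three imaging fields (mean silhouette
width), and tests whether the glucose-responder proportion is homogeneous
across fields.
"""

import warnings

import numpy as np

from calclust import (
    classical_mds,
    default_protocol,
    extract_features,
    field_proportion_test,
    generate_dataset,
    gmm_bic_select,
    label_clusters,
    paperlike_preset,
    qc_filter,
    rank_dims_by_silhouette,
    spearman_distance,
)
from calclust.cluster import NON_OSCILLATING, OSCILLATING
from calclust.preprocess import apply_qc, correct_dataset

protocol = default_protocol()
dataset, _ = generate_dataset(paperlike_preset(), seed=1)
kept = apply_qc(dataset, qc_filter(dataset, protocol))
corrected, _ = correct_dataset(kept, protocol)

distance = spearman_distance(corrected)
coords = classical_mds(distance, n_dims=10)
ranking = rank_dims_by_silhouette(coords, kept.field_ids, top_k=5)
print("MDS dimensions ranked by field separation (mean silhouette width):")
print(ranking.round(3).to_string(index=False))
print("Widths near zero mean no single trace-shape dimension is dominated by")
print("a field-wide batch effect; field structure here is compositional (below).")

table = extract_features(kept, protocol)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    model = gmm_bic_select(table, seed=1)
label_clusters(model, table)
flags = np.isin(
    [model.labels.get(a, "") for a in model.assignments], [OSCILLATING, NON_OSCILLATING]
)
res = field_proportion_test(flags, kept.field_ids)
print(f"\nresponder proportion homogeneity across fields ({res.method}):")
print(f"  chi2 = {res.statistic:.1f}, -log10 P = {res.neg_log10_p:.2f} (n = {res.n})")
print("A large -log10 P flags uneven dispersion of cell types across fields —")
print("the generator plants non-responder enrichment in field 3 on purpose.")
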