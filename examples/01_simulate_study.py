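"""Simulate a synthetic camera-trap study.

Generates correlated site covariates, community-level truth (species
effects drawn from community hyper-distributions), latent abundances and
detection histories for three carnivores at contrasting abundances, plus a
raw time-stamped event stream with sub-gap bursts and human/vehicle
background traffic.
"""

import numpy as np

from camuse import default_design, gen_community_truth, gen_detection_histories, \
    gen_site_covariates, standardize
from camuse.synthetic import default_nmixture_hypers

design = default_design(n_sites=150, n_occasions=16, seed=1)
covariates = standardize(
    gen_site_covariates(150, design.covariate_corr, seed=2)
)
truth = gen_community_truth(
    default_nmixture_hypers(len(design.covariate_names)),
    n_species=3, n_replicates=4, seed=3,
    species_names=design.species_names,
    covariate_names=design.covariate_names,
)
data, latent = gen_detection_histories(truth, covariates, design,
                                       "nmixture", seed=4)

print("sites:", data.n_sites, " occasions:", data.n_occasions,
      " species:", data.species)
print("total detections:", int(data.counts.sum()))
print("mean latent abundance per site:",
      np.round(latent.abundance.mean(axis=0), 2))
print("species detection intercepts (logit):",
      np.round(truth.detect_intercepts.mean(axis=0), 2))
# The abundances mirror the contrast the models are meant to resolve: one
# common, one intermediate, one scarce species; detections are sparse
# because per-individual, per-occasion detection is a few percent.
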