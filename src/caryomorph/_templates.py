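"""Frozen elliptic Fourier templates of the two grain views.

Normalized (centroid size 1) coefficient quadruples (a, b, c, d) for 10
harmonics, derived once from smooth parametric grain profiles: a pointed
egg with a smoothly flattened furrow side (lateral view) and a milder,
more symmetric taper (ventral view).  They anchor the synthetic-data
generator; all category, sowing, variety, year and grain effects are
offsets from these vectors.
"""

import numpy as np

TEMPLATE_COEFFS = {
    "lateral": np.array([
        [ 4.76505654e-02,  4.09637208e-03, -1.40620308e-03,  2.13831909e-02],
        [-1.82586507e-04, -4.90064905e-04, -2.03284672e-03,  9.65524656e-04],
        [ 4.00650908e-03,  1.06957929e-03, -6.83203988e-04,  2.28927993e-03],
        [-1.16248662e-04, -5.60559926e-04, -3.13226318e-04, -2.58008090e-05],
        [ 1.03294058e-03,  4.39865915e-04, -2.86261263e-04,  7.19959430e-04],
        [ 9.37581711e-06, -4.04398065e-04,  1.68316699e-05, -3.17821223e-05],
        [ 3.45325193e-04,  2.22820651e-04, -1.55482170e-04,  3.01604482e-04],
        [ 5.82953272e-05, -2.66874957e-04,  8.21295368e-05,  3.30796067e-06],
        [ 1.12116214e-04,  1.19703555e-04, -9.44134477e-05,  1.33561927e-04],
        [ 6.93298530e-05, -1.68172313e-04,  8.00947411e-05,  2.38215086e-05],
    ]),
    "ventral": np.array([
        [ 4.76864441e-02,  1.77306239e-03, -6.61420768e-04,  2.17447664e-02],
        [-1.92292852e-04, -2.12789873e-04, -8.64641294e-04,  9.59583073e-04],
        [ 4.15203381e-03,  4.69611301e-04, -2.89990218e-04,  2.36277651e-03],
        [-1.95674040e-04, -2.50531274e-04, -1.34643221e-04,  3.70509040e-05],
        [ 1.13969593e-03,  2.03368537e-04, -1.22758756e-04,  7.28449660e-04],
        [-1.07608716e-04, -1.89709657e-04,  8.43336668e-06, -3.35434236e-05],
        [ 4.35178685e-04,  1.11290568e-04, -6.60133772e-05,  3.03822191e-04],
        [-5.64110050e-05, -1.34442850e-04,  3.92145695e-05, -2.97937021e-05],
        [ 1.91898509e-04,  6.89331481e-05, -4.14179912e-05,  1.44872100e-04],
        [-2.84029732e-05, -9.34963542e-05,  4.04552164e-05, -1.92364083e-05],
    ]),
}

#: major/minor principal-axis extents of each normalized template outline
TEMPLATE_EXTENTS = {
    "lateral": (np.float64(0.107826530187343), np.float64(0.03958010967328966)),
    "ventral": (np.float64(0.10750767990755952), np.float64(0.04007918485626394)),
}
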