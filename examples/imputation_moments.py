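"""Moment recovery of the downshifted-Gaussian imputation.

Draws one large Gaussian column of log2 intensities, masks a random half,
imputes with the defaults (width 0.3, downshift 1.8), and verifies that the
imputed values land 1.8 observed SDs below the observed mean with 0.3 times
the observed spread — the left-censored stand-in distribution used for
missing-not-at-random phosphosite intensities.
"""

from phosphodiff.calibration import imputation_moments

moments = imputation_moments(n=100_000, seed=1)
print(f"imputed cells:        {moments['n_imputed']}")
print(f"estimated downshift:  {moments['downshift_estimate']:.4f}  (configured: 1.8 observed SDs)")
print(f"imputed/observed SD:  {moments['width_ratio']:.4f}  (configured: 0.3)")
print(
    "\nThe downshift places imputed values where undetected low-abundance "
    "sites plausibly sit; the narrow width keeps them from dominating the "
    "within-group variance of any single site."
)
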