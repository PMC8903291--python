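"""Colocalization: Pearson correlation as a function of granule overlap.

Renders two-channel scenes sweeping the number of shared granules at fixed
totals and prints the Pearson coefficient, optionally after rolling-ball
background subtraction (radius 50 px).
"""

from granulekit import gen_two_channel_scene, pearson_coloc, rolling_ball_subtract

print("shared/20  Pearson r")
for n_shared in (0, 5, 10, 15, 20):
    stack, _ = gen_two_channel_scene(n_shared=n_shared, n_only_a=20 - n_shared,
                                     n_only_b=20 - n_shared, snr=10, seed=11)
    a = rolling_ball_subtract(stack.plane(c=0), radius_px=50)
    b = rolling_ball_subtract(stack.plane(c=1), radius_px=50)
    res = pearson_coloc(a, b, preprocessing="rolling_ball r=50")
    print(f"   {n_shared:2d}      {res.pearson_r:+.3f}")
print("r rises monotonically with the shared-granule fraction; r = 1 would "
      "mean identical channels, r ~ 0 spatially unrelated ones.")
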