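"""Score one synthetic thigh-cuff manoeuvre with all three indices.

A manoeuvre with a known true autoregulation grade (ARI 5.0) is simulated:
the arterial pressure shows a sustained 25% drop at cuff release and the
flow velocity is the second-order model response. The model-free index, the
classic template-fit index, and the Rate of Regulation are then computed
from the two signals alone.
"""

from mfari import (
    SimSpec,
    classic_ari_corr,
    classic_ari_lsq,
    compute_ror,
    mfari_from_manoeuvre,
    published_model,
    simulate_manoeuvre,
)

spec = SimSpec(ari_true=5.0, abp_recovery_rate=0.1, seed=0)
m = simulate_manoeuvre(spec)
print(f"simulated manoeuvre: true ARI {spec.ari_true}, "
      f"release at t0={spec.t0} s, {m.abp.size} samples at {m.rate} Hz")

value, params, diag = mfari_from_manoeuvre(m, published_model())
print(f"mfARI      = {value:.2f}  "
      f"(k_S={params.k_s:.3f}, delta_tau={params.delta_tau:.1f} s, "
      f"phi={params.phi:.2f} deg)")

ari, mse = classic_ari_lsq(m)
print(f"classic ARI (least squares) = {ari:.0f}  (fit MSE {mse:.3g})")
print(f"classic ARI (correlation)   = {classic_ari_corr(m):.2f}")

r = compute_ror(m)
print(f"RoR = {r.ror:.3f} /s  (CVR slope {r.cvr_slope:.4f} /s over 1-3.6 s, "
      f"ABP drop {r.abp_drop:.3f})")
print()
print("All three agree on a mid-range autoregulation grade; the negative")
print("CVR slope reflects the resistance fall as vessels dilate after the")
print("pressure drop.")
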