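"""Generate one synthetic sit-down transfer trial and look at its streams.

The simulator produces the three streams the real measurement rig records:
the 20-channel 62 Hz seat-sensor count matrix, the 600 Hz force-plate CoP
trace and the 120 Hz head-marker height trace, together with the ground
truth that generated them.
"""

from careshift import MotionProfile, simulate_trial

profile = MotionProfile(seat_offset=(20.0, -40.0), descent_velocity=60.0)
rec = simulate_trial(profile=profile, seed=7)

print("ground truth:")
print(f"  seat offset      : {rec.truth.seat_offset} mm")
print(f"  descent velocity : {rec.truth.descent_velocity} mm/s")
print(f"  contact time     : {rec.truth.contact_time:.2f} s")

c = rec.counts
print(f"counts : {c.n_samples} samples x {c.n_channels} channels at {c.fs:g} Hz, "
      f"range {c.counts.min():.0f}..{c.counts.max():.0f}")
print(f"cop    : {rec.cop.t.size} samples at {rec.cop.fs:g} Hz")
print(f"marker : {rec.marker.t.size} samples at {rec.marker.fs:g} Hz")

# Counts sit at the parasitic baseline until the approach, then rise
# steeply as the gap closes and plateau once the clothing is compressed.
for t_query in (2.0, rec.truth.contact_time - 1.0, rec.truth.contact_time + 3.0):
    i = int(t_query * c.fs)
    print(f"  mean count at t={t_query:5.2f} s : {c.counts[i].mean():7.1f}")
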