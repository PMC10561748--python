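"""Reference-device indices: force-plate dCoP and head-marker v_z.

The force plate under the wheelchair sees the centre of pressure shift
when the recipient lands; dCoP is the mean CoP over the half-second
starting 5 s after contact, minus the pre-contact baseline.  The head
marker's third downward-velocity peak during the transfer (stand-up,
lateral move, descent) is the reference seating velocity v_z.
"""

from careshift import (
    MotionProfile,
    delta_cop,
    detect_contact,
    seating_velocity_vz,
    simulate_trial,
)

profile = MotionProfile(seat_offset=(-30.0, -40.0), head_peak_velocity=50.0)
rec = simulate_trial(profile=profile, seed=21, cop_noise_sd=0.3)

t1 = detect_contact(rec.cop)
d = delta_cop(rec.cop, t1)
vz = seating_velocity_vz(rec.marker)

print(f"detected contact t1 = {t1:.3f} s (truth {rec.truth.contact_time:.3f} s)")
print(f"dCoP = ({d.dx:.2f}, {d.dy:.2f}) mm  "
      f"(designed {rec.truth.designed_delta_cop} mm, "
      f"averaged over ({d.t2:.1f}, {d.t2 + 0.5:.1f}] s)")
print(f"v_z  = {vz:.2f} mm/s (configured {rec.truth.head_peak_velocity} mm/s)")

# Both reference indices recover their designed values, which is the
# round-trip check used to validate the seat-sensor indices against them.
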