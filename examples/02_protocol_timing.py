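"""Acquisition-timing arithmetic of the multiangle illumination device.

The servo that steers the fiber sockets bounds the usable laser pulse rate
(one angle step must complete between pulses), and the number of angles and
repeats per angle set the compound frame rate.
"""

import palsim as ps

omega = ps.servo_angular_velocity(60.0, 0.2)
print(f"servo sweeps 60 deg in 0.2 s  ->  omega_s = {omega:.2g} rad/s")
print(f"max laser PRF at 4 deg steps  ->  {ps.max_pulse_rate(omega, 4.0)} Hz")
print()
print("frame rates (laser PRF / (angles x repeats)):")
print(f"  10 Hz laser, 5 angles, 2 repeats -> {ps.frame_rate(10, 5, 2):g} fps")
print(f"  10 Hz laser, 5 angles, 1 repeat  -> {ps.frame_rate(10, 5, 1):g} fps")
print(f"  75 Hz laser, 5 angles, 1 repeat  -> {ps.frame_rate(75, 5, 1):g} fps")
print()
for name, proto in (("phantom", ps.PHANTOM_PROTOCOL),
                    ("finger/forearm", ps.FINGER_FOREARM_PROTOCOL),
                    ("mouse", ps.MOUSE_PROTOCOL)):
    print(f"{name}: angles {proto.angles()}, "
          f"{ps.total_frames(proto)} subframes per volume")
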