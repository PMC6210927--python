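"""Generate one labeled synthetic TUG recording and inspect its structure.

A standard execution is scripted as sit -> rise -> walk out -> turn -> walk
back -> turn -> sit down -> sit; the generator renders it into 100 Hz
accelerometer/gyroscope channels with the posture, gait and turning
signatures a belt-worn lower-back sensor shows.
"""

import itertools

import tugsense as ts

script = ts.ActivityScript(ts.standard_tug_script(), seed=42)
rec = ts.generate(script)

print(f"{len(rec)} samples at {rec.sample_rate:.0f} Hz ({rec.duration_s:.2f} s)")
print("label runs (activity, seconds):")
for label, group in itertools.groupby(rec.labels):
    print(f"  {label:13s} {len(list(group)) / rec.sample_rate:5.2f}")
# The phase runs between the two sits are one complete TUG execution; their
# total span is the ground-truth test duration the detector must recover.
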