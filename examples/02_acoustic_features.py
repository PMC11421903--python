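"""Extract the 94-feature mel battery and the f1-contour statistics.

The mel features summarise how energy is distributed over time and
frequency (gain-invariant, so recording level cannot leak into them);
the nine contour statistics describe the second-harmonic trajectory,
which is robust to recording-equipment differences.
"""

from rumblesig.features import (
    contour_stats,
    extract_mel_features,
    mel_spectrogram,
    trace_f1_contour,
)
from rumblesig.simulate import synthesize_call

w = synthesize_call(f1_mean_hz=32.0, contour_shape="rise", duration_s=3.0,
                    sample_rate_hz=2000, snr_db=20.0, seed=7)

ms = mel_spectrogram(w)
print(f"mel spectrogram: {ms.energies.shape[0]} bands x {ms.energies.shape[1]} frames")

v = extract_mel_features(ms)
print(f"{len(v)} mel features; first five:")
print(v.head().to_string())

c = trace_f1_contour(w)
s = contour_stats(c)
print(f"\n{int(c.voiced.sum())} voiced frames traced; contour statistics (Hz):")
print(s.to_string())
print("\nA 'rise' call sweeps upward, so the frequency at 75% of the call"
      " duration exceeds the one at 25%.")
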