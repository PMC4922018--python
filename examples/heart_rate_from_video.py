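"""Heart-rate extraction from a synthetic high-speed video.

Generates a 30-s, 300-fps recording of a heart beating at 170 bpm with a
2 Hz ventilation artifact and sensor noise, then runs the full pipeline:
ROI mean traces -> reference subtraction -> 21-frame moving average ->
diastole-minima detection -> interbeat intervals -> steady-state rate.
"""

from fishbeam import cardiometry as card
from fishbeam import synthetic as syn

params = syn.HeartSimParams(true_hr_bpm=170.0, duration_s=30.0, seed=11)
stack, rois, truth = syn.gen_heart_video(params, frame_shape=(96, 128))
print(f"video: {stack.n_frames} frames of {stack.shape} at {stack.fps:.0f} fps")

result = card.run_heartrate_pipeline(stack, rois, window_seconds=30.0)
s = result.summary
print(f"detected beats          : {result.beats.n_beats}")
print(f"steady-state heart rate : {s.mean_bpm:.1f} +/- {s.sd_bpm:.1f} bpm "
      f"(true rate {truth.nominal_hr_bpm:.0f} bpm)")
print(f"mean interbeat interval : {result.beats.ibis_frames.mean():.1f} frames "
      f"({result.beats.ibis_frames.mean() / stack.fps * 1000:.0f} ms)")
print("-> the ventilation artifact cancels in the reference subtraction;")
print("   the recovered rate should sit within ~1 bpm of the true 170 bpm.")
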