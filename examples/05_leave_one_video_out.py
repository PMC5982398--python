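"""Leave-one-video-out cross-validation.

Every fold holds out all subjects' trials of one stimulus and trains on the
remaining videos, so the model is always tested on an unseen stimulus.
A small 4-video set keeps this quick; each fold trains its own model.
"""

import emofusion as ef

cfg = ef.SimulationConfig(n_subjects=3, n_videos=4, duration_s=8.0, seed=9,
                          eeg_effect=2.0, gsr_effect=2.0, rating_noise_sd=0.0)
trials, _ = ef.simulate_dataset(cfg)
data = ef.prepare_trial_features(trials, ef.default_meta(cfg), "arousal2")

mcfg = ef.FusionModelConfig.reduced(n_classes=2, gsr_dim=data[0].gsr.size)
tcfg = ef.TrainingConfig(learning_rate=3e-2, max_iterations=150,
                         early_stop_patience=100, eval_interval=25, seed=0)
report = ef.evaluate_loocv(data, mcfg, tcfg)

print(f"{len(report.fold_accuracies)} folds (one per video), "
      f"{report.n_test} trials tested in total")
for video, acc in enumerate(report.fold_accuracies, start=1):
    print(f"  video {video} held out: fold accuracy {acc:.3f}")
print(f"LOOCV accuracy (mean over folds): {report.accuracy:.3f}")
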