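# fedherd

Federated CNN–LSTM stress monitoring for livestock sensor streams, at
desk scale.

## The problem

Wearable IoT sensors on dairy cattle produce continuous multimodal
streams — heart rate (bpm), body temperature (°C), an accelerometer
activity index, ambient temperature and humidity, GPS position. Early
stress detection from these streams is valuable, but raw physiological
data is privacy-sensitive at the farm level and expensive to move off
site. Federated learning (FL) sidesteps both problems: each farm
gateway ("edge client") trains a model on its own animals and shares
only parameter updates, which a server aggregates into a global model.

`fedherd` is a complete, reproducible simulation of that system for
researchers and students in precision livestock farming and federated
optimization. It provides:

* **A synthetic herd generator** emulating the statistical structure of
  multimodal cattle datasets: per-animal physiological baselines
  (non-IID across clients), a diurnal ambient cycle, Poisson-arrival
  stress episodes that elevate heart rate and temperature, sensor
  dropout runs and spike outliers, and ground-truth episode intervals.
* **The edge preprocessing pipeline**: per-animal forward/backward
  filling, z-score outlier screening (|z| > 3 drops the row), proxy
  stress labels (`is_stressed = 1` iff heart rate > 100 bpm **or** body
  temperature > 39.5 °C, in raw units), 30-minute trailing rolling
  features, min–max scaling to [0, 1] with frozen training bounds, and
  per-animal sliding windows.
* **A CNN–LSTM classifier written in plain numpy** — 1-D temporal
  convolution front-end, standard four-gate LSTM, sigmoid head — with
  hand-derived backpropagation through time (verified against finite
  differences) and mini-batch Adam.
* **FedAvg orchestration**: broadcast → E local epochs per client →
  sample-size-weighted aggregation over T communication rounds, plus a
  matched centralized baseline and an analytic per-round
  uplink/downlink byte ledger.
* **Evaluation**: window-level confusion matrix, accuracy, precision,
  recall, F1, and a federated-vs-centralized comparison table.

## The model

Each normalized sensor window `x ∈ [0,1]^{L×F}` passes through a valid
1-D convolution with ReLU, `y = ReLU(w ∗ x + b)`, then an LSTM

    i_t = σ(w_i·[h_{t−1}, x_t] + b_i)
    f_t = σ(w_f·[h_{t−1}, x_t] + b_f)
    o_t = σ(w_o·[h_{t−1}, x_t] + b_o)
    C_t = f_t ⊙ C_{t−1} + i_t ⊙ tanh(w_c·[h_{t−1}, x_t] + b_c)
    h_t = o_t ⊙ tanh(C_t)

whose final hidden state feeds a dense+ReLU layer and a single sigmoid
logit (equivalent to a two-class softmax). Client y minimizes the mean
binary cross-entropy over its |X_y| windows, and the server forms

    k^{t+1} = Σ_y (|X_y| / Σ_j |X_j|) · k_y^t .

The shipped default architecture (32 conv channels, kernel 3, 256 LSTM
units, 64 dense units) serializes to ≈1.2 MB at 32-bit — so a 10-client,
50-round run moves ≈600 MB of uplink, which the ledger accounts for
analytically.

## Worked example

```python
import fedherd as fh

cfg = fh.validate_config({
    "federated": {"rounds": 20},
    "model": fh.desk_model_config().to_dict(),   # small model for a laptop CPU
    "output_dir": "runs/demo",
    "master_seed": 42,
})
summary = fh.run_experiment(cfg)
print(summary["report"])
```

which prints (a few minutes on one CPU core):

```
Model comparison (window-level, decision threshold 0.5)

               model accuracy_pct accuracy precision recall     f1 uplink_mb downlink_mb
  federated_cnn_lstm         99.4   0.9938    0.9667 0.9667 0.9667      4.58        4.58
centralized_cnn_lstm        100.0   1.0000    1.0000 1.0000 1.0000      0.00        0.00

Traffic in MB (1 MB = 2^20 bytes); centralized runs move no model traffic.
```

Reading the output: 20 animals were simulated for 7 days at 15-minute
sampling; 4 held-out animals' windows form the test set. The federated
model detects stress windows with F1 0.97 at 99.4% accuracy — within
one percentage point of the centralized model trained on the pooled
data — while moving only parameter updates (4.58 MB of uplink for this
small model over 20 rounds; the full-size model over 50 rounds moves
~600 MB). The same experiment is scriptable from a shell:

```bash
fedherd full-run -c config.yaml -o runs/demo --seed 42
fedherd report runs/demo
```

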