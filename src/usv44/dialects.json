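{
  "version": 1,
  "dialects": {
    "native": {
      "time_unit": "s",
      "frequency_unit": "hz",
      "columns": {
        "call_id": "call_id",
        "rat_id": "rat_id",
        "session_id": "session_id",
        "onset_s": "onset",
        "duration_s": "duration",
        "peak_freq_hz": "peak_frequency",
        "mean_power_db": "mean_power",
        "call_type": "call_type",
        "subtype": "subtype"
      },
      "header": [
        "call_id",
        "rat_id",
        "session_id",
        "onset_s",
        "duration_s",
        "peak_freq_hz",
        "mean_power_db",
        "call_type",
        "subtype"
      ]
    },
    "avisoft_like": {
      "time_unit": "ms",
      "frequency_unit": "khz",
      "columns": {
        "id": "call_id",
        "start_ms": "onset",
        "duration_ms": "duration",
        "peakfreq_khz": "peak_frequency",
        "meanpower_db": "mean_power"
      },
      "header": ["id", "start_ms", "duration_ms", "peakfreq_khz", "meanpower_db"]
    },
    "deepsqueak_like": {
      "time_unit": "s",
      "frequency_unit": "khz",
      "columns": {
        "ID": "call_id",
        "Begin Time (s)": "onset",
        "Call Length (s)": "duration",
        "Peak Freq (kHz)": "peak_frequency",
        "Mean Power (dB/Hz)": "mean_power"
      },
      "header": [
        "ID",
        "Begin Time (s)",
        "Call Length (s)",
        "Peak Freq (kHz)",
        "Mean Power (dB/Hz)"
      ]
    }
  }
}
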