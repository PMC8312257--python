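{
  "dialect_version": "1.0",
  "description": "Documented JSON dialect for rcstream session folders. A session is 11 JSON files. Packetized streams (RawDataTD, RawDataAccel, RawDataPower) hold a 'Packets' list; the remaining files hold a 'Records' list. All times named *UnixTime/Time are unix milliseconds unless stated otherwise.",
  "files": {
    "RawDataTD.json": {
      "kind": "packetized",
      "packet_fields": {
        "SystemTick": "int, hardware counter in 1e-4 s ticks, modulo 2^16 (~6.5535 s per cycle); timing refers to the LAST sample of the packet",
        "Timestamp": "int, firmware seconds elapsed since 2000-03-01T00:00:00Z (unix offset 951868800 s); 1 s resolution",
        "PacketGenTime": "int, API estimate of packet creation, unix milliseconds; jitters between packets",
        "PacketRxUnixTime": "int, unix milliseconds of packet receipt at the tablet; inaccurate after drops, carried but unused",
        "DataTypeSequence": "int, per-stream packet counter modulo 256",
        "SampleRate": "int code, see sample_rate_codebook",
        "ChannelSamples": "object: channel key ('0'..'3') -> array of millivolt samples; all channels equal length"
      }
    },
    "RawDataAccel.json": {
      "kind": "packetized",
      "packet_fields": "as RawDataTD but SampleRateHz (plain Hz number, one of 4/8/16/32/64) and ChannelSamples keys 'X','Y','Z' in g"
    },
    "RawDataPower.json": {
      "kind": "packetized",
      "packet_fields": "as RawDataAccel; SampleRateHz = 1/fft_interval; ChannelSamples keys 'Band0'.. in RCS units; top-level 'Bands' echoes band edges, gain G and source channel"
    },
    "RawDataFFT.json": {
      "kind": "records",
      "record_fields": {"Time": "unix ms of the window's last sample", "Amplitude": "array of single-sided FFT amplitudes (RCS units)"}
    },
    "AdaptiveLog.json": {
      "kind": "records",
      "record_fields": {"Time": "unix ms", "State": "int detector state", "Output": "float detector output", "CurrentMa": "float stimulation current"}
    },
    "DeviceSettings.json": {
      "kind": "records",
      "record_fields": {
        "Time": "unix ms at which these settings took effect",
        "TDSettings": "object: channel key -> {SampleRate (code), GainCode (int, config trimmer ch gain), Hpf (Hz), Lpf (Hz), Contacts ('+a-c' electrode pair)}",
        "FFTConfig": "{Size: 64|256|1024, IntervalMs, WindowLoad: 25|50|100}",
        "PowerBands": "[{Lo, Hi (Hz), GainG, Channel}]",
        "Adaptive": "opaque adaptive-detector configuration",
        "Metadata": "{UtcOffsetMinutes, DeviceId, SessionId}"
      }
    },
    "StimLog.json": {
      "kind": "records",
      "record_fields": {"Time": "unix ms", "Group": "str", "Contacts": "'+a-c'", "AmplitudeMa": "float", "PulseWidthUs": "int", "RateHz": "float"}
    },
    "TimeSync.json": {"kind": "records", "record_fields": {"Time": "unix ms", "TimestampEpochUnixSeconds": "int", "UtcOffsetMinutes": "int"}},
    "EventLog.json": {"kind": "records", "record_fields": {"Time": "unix ms", "EventType": "str", "Payload": "str"}},
    "ErrorLog.json": {"kind": "records", "record_fields": {"Time": "unix ms", "Code": "str", "Detail": "str"}},
    "DiagnosticsLog.json": {"kind": "records", "record_fields": {"Time": "unix ms", "BatteryPct": "int", "TelemetryQuality": "str"}}
  },
  "sample_rate_codebook": {"0": 250, "1": 500, "2": 1000, "240": "disabled"},
  "sidecars": {
    "_groundtruth.json": "written only by the simulator; true unix time of every generated sample, clean signals and the packet drop/reorder log. Never present in real device data."
  }
}
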