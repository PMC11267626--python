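{
  "trait_correlation": 0.58,
  "source": {
    "name": "sdq_like",
    "n_categories": 3,
    "items": [
      {
        "item_id": "src_1",
        "a": 1.3,
        "b": [
          0.1,
          1.3
        ]
      },
      {
        "item_id": "src_2",
        "a": 1.7,
        "b": [
          0.5,
          1.7
        ]
      },
      {
        "item_id": "src_3",
        "a": 2.0,
        "b": [
          0.9,
          2.0
        ]
      },
      {
        "item_id": "src_4",
        "a": 2.4,
        "b": [
          0.3,
          1.5
        ]
      },
      {
        "item_id": "src_5",
        "a": 2.9,
        "b": [
          0.7,
          2.2
        ]
      }
    ]
  },
  "target": {
    "name": "cbcl_like",
    "n_categories": 3,
    "items": [
      {
        "item_id": "tgt_1",
        "a": 1.06,
        "b": [
          0.4,
          1.8
        ]
      },
      {
        "item_id": "tgt_2",
        "a": 1.18,
        "b": [
          1.2,
          2.6
        ]
      },
      {
        "item_id": "tgt_3",
        "a": 1.3,
        "b": [
          0.8,
          2.2
        ]
      },
      {
        "item_id": "tgt_4",
        "a": 1.42,
        "b": [
          1.6,
          3.0
        ]
      },
      {
        "item_id": "tgt_5",
        "a": 1.42,
        "b": [
          0.6,
          2.0
        ]
      },
      {
        "item_id": "tgt_6",
        "a": 1.53,
        "b": [
          1.4,
          2.8
        ]
      },
      {
        "item_id": "tgt_7",
        "a": 1.53,
        "b": [
          1.0,
          2.4
        ]
      },
      {
        "item_id": "tgt_8",
        "a": 1.65,
        "b": [
          1.8,
          3.2
        ]
      },
      {
        "item_id": "tgt_9",
        "a": 1.77,
        "b": [
          0.9,
          2.3
        ]
      },
      {
        "item_id": "tgt_10",
        "a": 1.89,
        "b": [
          1.3,
          2.7
        ]
      },
      {
        "item_id": "tgt_11",
        "a": 2.12,
        "b": [
          1.1,
          2.5
        ]
      }
    ]
  }
}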