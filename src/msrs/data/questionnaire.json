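{
 "items": [
  {
   "item_id": 1,
   "text": "item 01",
   "reverse_keyed": false
  },
  {
   "item_id": 2,
   "text": "item 02 (infrequent-direction wording)",
   "reverse_keyed": true
  },
  {
   "item_id": 3,
   "text": "item 03",
   "reverse_keyed": false
  },
  {
   "item_id": 4,
   "text": "item 04",
   "reverse_keyed": false
  },
  {
   "item_id": 5,
   "text": "item 05 (infrequent-direction wording)",
   "reverse_keyed": true
  },
  {
   "item_id": 6,
   "text": "item 06",
   "reverse_keyed": false
  },
  {
   "item_id": 7,
   "text": "item 07",
   "reverse_keyed": false
  },
  {
   "item_id": 8,
   "text": "item 08",
   "reverse_keyed": false
  },
  {
   "item_id": 9,
   "text": "item 09",
   "reverse_keyed": false
  },
  {
   "item_id": 10,
   "text": "item 10",
   "reverse_keyed": false
  },
  {
   "item_id": 11,
   "text": "item 11",
   "reverse_keyed": false
  },
  {
   "item_id": 12,
   "text": "item 12",
   "reverse_keyed": false
  },
  {
   "item_id": 13,
   "text": "item 13",
   "reverse_keyed": false
  },
  {
   "item_id": 14,
   "text": "item 14 (infrequent-direction wording)",
   "reverse_keyed": true
  },
  {
   "item_id": 15,
   "text": "item 15",
   "reverse_keyed": false
  },
  {
   "item_id": 16,
   "text": "item 16",
   "reverse_keyed": false
  },
  {
   "item_id": 17,
   "text": "item 17",
   "reverse_keyed": false
  },
  {
   "item_id": 18,
   "text": "item 18",
   "reverse_keyed": false
  },
  {
   "item_id": 19,
   "text": "item 19",
   "reverse_keyed": false
  },
  {
   "item_id": 20,
   "text": "item 20",
   "reverse_keyed": false
  },
  {
   "item_id": 21,
   "text": "item 21",
   "reverse_keyed": false
  },
  {
   "item_id": 22,
   "text": "item 22",
   "reverse_keyed": false
  },
  {
   "item_id": 23,
   "text": "item 23",
   "reverse_keyed": false
  },
  {
   "item_id": 24,
   "text": "item 24",
   "reverse_keyed": false
  },
  {
   "item_id": 25,
   "text": "item 25",
   "reverse_keyed": false
  },
  {
   "item_id": 26,
   "text": "item 26 (infrequent-direction wording)",
   "reverse_keyed": true
  },
  {
   "item_id": 27,
   "text": "item 27",
   "reverse_keyed": false
  },
  {
   "item_id": 28,
   "text": "item 28 (infrequent-direction wording)",
   "reverse_keyed": true
  },
  {
   "item_id": 29,
   "text": "item 29",
   "reverse_keyed": false
  },
  {
   "item_id": 30,
   "text": "item 30",
   "reverse_keyed": false
  },
  {
   "item_id": 31,
   "text": "item 31",
   "reverse_keyed": false
  },
  {
   "item_id": 32,
   "text": "item 32",
   "reverse_keyed": false
  },
  {
   "item_id": 33,
   "text": "item 33",
   "reverse_keyed": false
  },
  {
   "item_id": 34,
   "text": "item 34",
   "reverse_keyed": false
  },
  {
   "item_id": 35,
   "text": "item 35",
   "reverse_keyed": false
  },
  {
   "item_id": 36,
   "text": "item 36",
   "reverse_keyed": false
  }
 ]
}
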