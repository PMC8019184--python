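{"type": "FeatureCollection", "features": [{"type": "Feature", "properties": {"season": "breeding", "crs_flag": "planar"}, "geometry": {"type": "Polygon", "coordinates": [[[7212.2, 9500.0], [7415.7, 8470.9], [6580.6, 7746.7], [5582.0, 7244.2], [4444.1, 7345.5], [3604.4, 7951.9], [2459.7, 8417.8], [2718.5, 9500.0], [2675.1, 10490.4], [3418.0, 11254.9], [4506.0, 11414.7], [5595.7, 11808.7], [6796.9, 11493.2], [7120.6, 10403.4], [7212.2, 9500.0]]]}}, {"type": "Feature", "properties": {"season": "nonbreeding", "crs_flag": "planar"}, "geometry": {"type": "Polygon", "coordinates": [[[9246.6, 2400.0], [8785.1, 1250.4], [7702.1, 570.6], [6617.9, 79.4], [5286.7, -278.6], [4226.6, 493.9], [3139.8, 1219.4], [3528.1, 2400.0], [3203.1, 3554.5], [4331.9, 4193.0], [5352.9, 4830.3], [6529.0, 4386.7], [8045.1, 4598.1], [8533.0, 3445.6], [9246.6, 2400.0]]]}}]}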