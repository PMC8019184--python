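{"type": "FeatureCollection", "features": [{"type": "Feature", "properties": {"season": "breeding", "crs_flag": "planar"}, "geometry": {"type": "Polygon", "coordinates": [[[0.0, 11092.2], [933.3, 11094.0], [1866.7, 10909.7], [2800.0, 10765.1], [3733.3, 10619.0], [4666.7, 10826.5], [5600.0, 10842.3], [6533.3, 10613.5], [7466.7, 10615.7], [8400.0, 11214.5], [9333.3, 10996.0], [10266.7, 10732.7], [11200.0, 10859.0], [12133.3, 11198.7], [13066.7, 11150.5], [14000.0, 11116.9], [14000.0, 9414.2], [13066.7, 8969.3], [12133.3, 9403.3], [11200.0, 8865.5], [10266.7, 8850.9], [9333.3, 9271.8], [8400.0, 8866.8], [7466.7, 8987.1], [6533.3, 9374.5], [5600.0, 8860.8], [4666.7, 9244.0], [3733.3, 9065.0], [2800.0, 9376.7], [1866.7, 8988.7], [933.3, 9104.4], [0.0, 9167.8], [0.0, 11092.2]]]}}, {"type": "Feature", "properties": {"season": "nonbreeding", "crs_flag": "planar"}, "geometry": {"type": "Polygon", "coordinates": [[[500.0, 3526.7], [1433.3, 3390.3], [2366.7, 3408.3], [3300.0, 3412.1], [4233.3, 3841.2], [5166.7, 3592.9], [6100.0, 3622.0], [7033.3, 3381.0], [7966.7, 3625.9], [8900.0, 3236.1], [9833.3, 3186.2], [10766.7, 3745.1], [11700.0, 3156.2], [12633.3, 3835.1], [13566.7, 3728.9], [14500.0, 3699.6], [14500.0, 1626.6], [13566.7, 1439.2], [12633.3, 1542.2], [11700.0, 1752.2], [10766.7, 1243.7], [9833.3, 1775.2], [8900.0, 1472.1], [7966.7, 1318.4], [7033.3, 1501.9], [6100.0, 1719.6], [5166.7, 1764.4], [4233.3, 1410.8], [3300.0, 1547.3], [2366.7, 1255.1], [1433.3, 1704.8], [500.0, 1816.3], [500.0, 3526.7]]]}}]}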