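{"type": "FeatureCollection", "features": [{"type": "Feature", "properties": {"season": "breeding", "crs_flag": "planar"}, "geometry": {"type": "Polygon", "coordinates": [[[0.0, 11613.2], [1333.3, 12104.5], [2666.7, 11201.5], [4000.0, 12102.5], [5333.3, 11389.3], [6666.7, 11514.1], [8000.0, 11967.0], [9333.3, 11498.3], [10666.7, 11655.5], [12000.0, 11070.9], [13333.3, 11883.9], [14666.7, 11642.7], [16000.0, 11409.3], [17333.3, 11923.0], [18666.7, 11379.6], [20000.0, 11547.9], [20000.0, 8830.2], [18666.7, 8382.0], [17333.3, 7873.7], [16000.0, 8780.1], [14666.7, 8649.9], [13333.3, 8353.8], [12000.0, 8148.2], [10666.7, 7882.9], [9333.3, 7861.6], [8000.0, 8416.6], [6666.7, 8645.9], [5333.3, 8119.6], [4000.0, 8666.2], [2666.7, 8732.1], [1333.3, 8508.5], [0.0, 8809.9], [0.0, 11613.2]]]}}, {"type": "Feature", "properties": {"season": "nonbreeding", "crs_flag": "planar"}, "geometry": {"type": "Polygon", "coordinates": [[[500.0, 3216.3], [1833.3, 3260.2], [3166.7, 3873.9], [4500.0, 3014.4], [5833.3, 3619.1], [7166.7, 3772.0], [8500.0, 3128.6], [9833.3, 2970.6], [11166.7, 3232.2], [12500.0, 3687.3], [13833.3, 3574.1], [15166.7, 3083.6], [16500.0, 3419.8], [17833.3, 3701.5], [19166.7, 3408.1], [20500.0, 3658.5], [20500.0, -357.5], [19166.7, 454.7], [17833.3, 570.6], [16500.0, 567.4], [15166.7, -130.6], [13833.3, 134.6], [12500.0, -404.8], [11166.7, 316.4], [9833.3, -227.9], [8500.0, -365.5], [7166.7, 86.8], [5833.3, 283.3], [4500.0, 472.2], [3166.7, 229.0], [1833.3, -117.8], [500.0, -456.2], [500.0, 3216.3]]]}}]}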